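"""Behavioral statistics: KDE clustering, d', intervals, tables, timing."""

import numpy as np
import pandas as pd
import pytest

from mesocage.behavior_stats import (
    KdeClusterConfig,
    aggregate_summary,
    daily_counts,
    day_night_fraction,
    day_night_success,
    density_at,
    dprime,
    interval_stats,
    interval_uniformity,
    isolated_crossing_sigma,
    kde_clusters,
    load_printed_summary,
    merge_break_gap,
    table_summary,
)
from mesocage.eventlog import HeadfixSession, Trial, parse_sessions
from mesocage.mouse_sim import AgentParams, simulate_colony


# --------------------------------------------------------------------- KDE


def test_isolated_peak_crossing_near_published_2p4_sigma():
    """The 5% crossing of a unit Gaussian sits at sqrt(2 ln 20) ~ 2.45 sigma."""
    x = isolated_crossing_sigma(0.05)
    assert x == pytest.approx(np.sqrt(2 * np.log(20)))
    assert abs(x - 2.4) < 0.1  # the rounded figure quoted for this analysis


def test_merge_break_gap_within_4_to_5_minutes():
    gap = merge_break_gap(50.0, 0.05)
    assert gap == pytest.approx(2 * 50 * np.sqrt(2 * np.log(40)))
    assert 240.0 <= gap <= 300.0


def test_kde_cluster_examples():
    assert kde_clusters([]).n_clusters == 0
    single = kde_clusters([5.0])
    assert single.n_clusters == 1 and single.sizes.tolist() == [1]
    assert kde_clusters([0.0, 100.0]).n_clusters == 1  # midpoint density 1.21 > 0.05
    assert kde_clusters([0.0, 400.0]).n_clusters == 2  # beyond the 271.6 s break gap


def test_kde_cluster_mouse_counts():
    res = kde_clusters([0.0, 20.0, 1000.0], tags=["a", "b", "a"])
    assert res.n_clusters == 2
    assert res.mouse_counts.tolist() == [2, 1]


def _grid_oracle(times, sigma=50.0, threshold=0.05):
    """Brute-force 1 s-grid density clustering (independent of the fast path)."""
    times = np.sort(np.asarray(times, float))
    grid = np.arange(times[0] - 1.0, times[-1] + 2.0, 1.0)
    dens = np.zeros_like(grid)
    for g_i, g in enumerate(grid):
        dens[g_i] = np.sum(np.exp(-((g - times) ** 2) / (2 * sigma**2)))
    above = dens >= threshold
    labels = []
    current = -1
    for t in times:
        gi = int(np.searchsorted(grid, t) - 1)
        # new cluster whenever the density dipped below threshold since the
        # previous event
        if not labels:
            current = 0
        else:
            prev = int(np.searchsorted(grid, last_t) - 1)
            if not above[prev : gi + 1].all():
                current += 1
        labels.append(current)
        last_t = t
    return np.asarray(labels)


def test_kde_cluster_agrees_with_grid_oracle():
    rng = np.random.default_rng(123)
    for _ in range(20):
        n = rng.integers(2, 50)
        times = np.sort(rng.uniform(0, 5000, size=n))
        fast = kde_clusters(times).labels
        slow = _grid_oracle(times)
        assert np.array_equal(fast, slow), times


def test_density_helper_matches_direct_sum():
    events = np.array([0.0, 30.0, 400.0])
    t = np.array([10.0, 200.0])
    expect = np.exp(-((t[:, None] - events[None]) ** 2) / (2 * 50.0**2)).sum(axis=1)
    np.testing.assert_allclose(density_at(t, events, 50.0), expect)


# --------------------------------------------------------------------- d'


def test_dprime_no_discrimination_is_zero():
    codes = [2] * 50 + [-2] * 50 + [-1] * 50 + [1] * 50
    assert dprime(codes).dprime == pytest.approx(0.0, abs=1e-12)


def test_dprime_matches_normal_quantile_oracle():
    """hit 0.9 / FA 0.2 gives z(0.9) - z(0.2) = 2.1232."""
    codes = [2] * 90 + [-2] * 10 + [-1] * 20 + [1] * 80
    from scipy.stats import norm

    expected = norm.ppf(0.9) - norm.ppf(0.2)
    res = dprime(codes)
    assert res.dprime == pytest.approx(expected, abs=1e-12)
    assert res.dprime == pytest.approx(2.1232, abs=1e-3)


def test_dprime_excludes_early_licks_and_clamps_extremes():
    codes = [2] * 10 + [-4] * 40 + [1] * 10 + [-3] * 7 + [-1] * 0
    res = dprime(codes + [-1])
    assert res.n_go == 10  # -4 trials disregarded
    assert res.hit_rate == pytest.approx(0.95)  # all-correct clamped to 1 - 1/(2*10)


def test_dprime_requires_both_trial_kinds():
    with pytest.raises(ValueError):
        dprime([2, -2, -4])


# ------------------------------------------------------------- participation


def test_daily_counts_matches_simulator_truth(small_colony):
    store, truth = small_colony
    sessions = parse_sessions(store)
    table = daily_counts(store, "headfixes", sessions=sessions)
    truth_fixed = truth.sessions[truth.sessions.fixed]
    expected = (
        truth_fixed.assign(day=(truth_fixed.start // 86400).astype(int))
        .groupby(["tag", "day"])
        .size()
    )
    got = table.set_index(["tag", "day"])["value"]
    assert got.astype(int).to_dict() == expected.to_dict()


def test_daily_counts_time_fixed_single_session():
    rec_sessions = [
        HeadfixSession(tag="a", start=100.0, end=140.0, fixed=True),
    ]
    from mesocage.eventlog import EventRecord, EventStore

    store = EventStore([EventRecord(100.0, "a", "entry")])
    table = daily_counts(store, "time_fixed", sessions=rec_sessions)
    assert table.value.iloc[0] == pytest.approx(40.0)


def test_daily_counts_rejects_unknown_kind(small_colony):
    store, _ = small_colony
    with pytest.raises(ValueError, match="kind"):
        daily_counts(store, "naps")


# ----------------------------------------------------------------- intervals


def _zero_length_session(tag, start):
    return HeadfixSession(tag=tag, start=start, end=start + 1e-6, fixed=True)


def test_interval_stats_start_to_start_example():
    sessions = [_zero_length_session("a", t) for t in (0.0, 10.0, 20.0)]
    res = interval_stats(sessions, definition="start_to_start")
    np.testing.assert_allclose(res.same_mouse["a"], [10.0, 10.0])
    assert res.same_medians["a"] == pytest.approx(10.0)


def test_interval_stats_cross_mouse_example():
    sessions = [_zero_length_session("a", 0.0), _zero_length_session("b", 7.0)]
    res = interval_stats(sessions)
    assert res.cross_mouse.tolist() == [7.0]


def test_interval_stats_too_few_sessions():
    res = interval_stats([_zero_length_session("a", 0.0)])
    assert res.same_mouse == {} and res.cross_mouse.size == 0


# ----------------------------------------------------------------- day/night


def test_day_night_fraction_extremes():
    night = [_zero_length_session("a", 2 * 3600.0 + i * 86400) for i in range(4)]
    assert day_night_fraction(night) == 1.0
    mixed = night + [_zero_length_session("a", 12 * 3600.0 + i * 86400) for i in range(4)]
    assert day_night_fraction(mixed) == 0.5


def test_night_fraction_estimator_recovers_simulated_bias(small_colony):
    store, truth = small_colony
    sessions = parse_sessions(store)
    est = day_night_fraction(sessions)
    assert est == pytest.approx(truth.sessions.night.mean(), abs=0.02)


def _session_with_go_trials(tag, start, n, n_correct):
    trials = []
    for i in range(n):
        trials.append(
            Trial(cue_time=start + 5 * i, cue_kind="go", withhold_duration=2.0, delay=0.9,
                  licks=[1.2] if i < n_correct else [], outcome=2 if i < n_correct else -2)
        )
    return HeadfixSession(tag=tag, start=start, end=start + 5 * n + 1, fixed=True, trials=trials)


def test_day_night_success_balanced_is_ratio_one():
    sessions = []
    for day in range(12):
        base = day * 86400.0
        sessions.append(_session_with_go_trials("a", base + 10 * 3600, 10, 6))  # day phase
        sessions.append(_session_with_go_trials("a", base + 22 * 3600, 10, 6))  # night phase
    df = day_night_success(sessions, min_days=10)
    assert len(df) == 1
    assert df.mean_ratio.iloc[0] == pytest.approx(1.0)
    assert df.p.iloc[0] > 0.9


def test_day_night_success_detects_day_bias():
    sessions = []
    for day in range(12):
        base = day * 86400.0
        sessions.append(_session_with_go_trials("a", base + 10 * 3600, 10, 8))
        sessions.append(_session_with_go_trials("a", base + 22 * 3600, 10, 4))
    df = day_night_success(sessions, min_days=10)
    assert df.mean_ratio.iloc[0] == pytest.approx(2.0)
    assert df.p.iloc[0] < 0.01


def test_day_night_success_excludes_short_records():
    sessions = []
    for day in range(5):
        base = day * 86400.0
        sessions.append(_session_with_go_trials("a", base + 10 * 3600, 10, 6))
        sessions.append(_session_with_go_trials("a", base + 22 * 3600, 10, 6))
    assert day_night_success(sessions, min_days=10).empty


# -------------------------------------------------------------- summary table


def test_printed_male_aggregates():
    """The shipped good-performer rows reproduce the published aggregates."""
    df = aggregate_summary(load_printed_summary("male"))
    agg = df.set_index("tag")
    assert round(agg.loc["AVG", "headfixes_per_day"], 1) == 27.5
    assert round(agg.loc["STDEV", "headfixes_per_day"], 1) == 17.3
    assert int(agg.loc["SUM", "total_headfixes"]) == 33087
    assert round(agg.loc["AVG", "minutes_per_day"], 1) == 17.7
    assert round(agg.loc["AVG", "go_success_last5"], 1) == 54.7


def test_printed_female_aggregates():
    df = aggregate_summary(load_printed_summary("female"))
    agg = df.set_index("tag")
    assert round(agg.loc["AVG", "daily_trials_5day"], 2) == 113.68
    assert int(agg.loc["SUM", "total_headfixes"]) == 5423


def test_single_mouse_stdev_is_empty():
    df = aggregate_summary(load_printed_summary("male").head(1))
    agg = df.set_index("tag")
    assert np.isnan(agg.loc["STDEV", "headfixes_per_day"])
    assert agg.loc["AVG", "headfixes_per_day"] == pytest.approx(15.6)


def test_table_summary_counts_match_truth(small_colony):
    store, truth = small_colony
    df = table_summary(store, good_performer_min_minutes=0.0)
    truth_fixed = truth.sessions[truth.sessions.fixed].groupby("tag").size()
    for _, row in df.iterrows():
        assert row.total_headfixes == truth_fixed.get(row.tag, 0)
        assert row.headfixes_per_day == pytest.approx(row.total_headfixes / row.days_headfix)


# ------------------------------------------------------------------- timing


def test_interval_uniformity_uniform_null_accepts():
    rng = np.random.default_rng(0)
    times = rng.uniform(0, 86400, size=10_000)
    res = interval_uniformity(times, dist="uniform")
    assert res.statistic < res.critical_values[-1]  # below the 1% level


def test_interval_uniformity_clustered_rejects():
    rng = np.random.default_rng(0)
    # sessions piled into a 2 h nightly window
    times = 20 * 3600 + rng.uniform(0, 2 * 3600, size=5000)
    for dist in ("uniform", "norm"):
        res = interval_uniformity(times, dist=dist)
        assert res.statistic > res.critical_values[-1] * 10


def test_interval_uniformity_needs_enough_events():
    with pytest.raises(ValueError):
        interval_uniformity([1.0, 2.0, 3.0])
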