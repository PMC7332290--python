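"""Behavioral statistics for home-cage head-fixation data.

Covers the full descriptive battery: daily participation counts, same- and
cross-mouse inter-headfix interval structure, kernel-density clustering of
headfix events in time, day/night activity and performance splits,
signal-detection d' for the go/no-go task, per-mouse summary tables with
AVG/STDEV/SUM aggregate rows, and an Anderson-Darling check that headfix
timing is not uniformly/normally distributed over the day.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .eventlog import EventStore, HeadfixSession, parse_sessions

__all__ = [
    "KdeClusterConfig",
    "ClusterResult",
    "kde_clusters",
    "isolated_crossing_sigma",
    "merge_break_gap",
    "DPrimeResult",
    "dprime",
    "daily_counts",
    "IntervalStats",
    "interval_stats",
    "day_night_fraction",
    "day_night_success",
    "table_summary",
    "aggregate_summary",
    "load_printed_summary",
    "interval_uniformity",
]

SECONDS_PER_DAY = 86400.0
LIGHTS_ON = 7.0  # facility clock hour; 12 h light cycle
LIGHTS_OFF = 19.0


def _hour(t: float) -> float:
    return (t / 3600.0) % 24.0


def _is_night(t: float, lights_on: float = LIGHTS_ON, lights_off: float = LIGHTS_OFF) -> bool:
    h = _hour(t)
    return not (lights_on <= h < lights_off)


# --------------------------------------------------------------------------
# KDE clustering of headfix events


@dataclass(frozen=True)
class KdeClusterConfig:
    """1-D kernel-density clustering parameters.

    Each headfix start is replaced by a unit-amplitude Gaussian of standard
    deviation ``sigma`` (default 50 s, the typical duration of a single
    headfix including entering and exiting); the summed density is
    thresholded at ``threshold_fraction`` (default 5%) of an isolated
    peak's amplitude to find cluster breaks.
    """

    sigma: float = 50.0
    threshold_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must be in (0, 1)")


def isolated_crossing_sigma(threshold_fraction: float = 0.05) -> float:
    """Distance (in sigmas) at which an isolated unit Gaussian falls to the
    threshold: sqrt(2 ln(1/threshold)); ~2.45 sigma at 5%."""
    return float(np.sqrt(2.0 * np.log(1.0 / threshold_fraction)))


def merge_break_gap(sigma: float = 50.0, threshold_fraction: float = 0.05) -> float:
    """Largest gap (s) at which two isolated events still merge into one
    cluster: the midpoint density of two unit Gaussians equals the
    threshold at gap = 2 sigma sqrt(2 ln(2/threshold)) (~271.6 s at the
    defaults, i.e. cluster breaks appear after 4-5 min without a headfix).
    """
    return float(2.0 * sigma * np.sqrt(2.0 * np.log(2.0 / threshold_fraction)))


@dataclass
class ClusterResult:
    """Cluster assignment of time-ordered events."""

    labels: np.ndarray  # cluster index per event
    sizes: np.ndarray  # events per cluster
    mouse_counts: np.ndarray | None = None  # distinct tags per cluster

    @property
    def n_clusters(self) -> int:
        return int(self.sizes.size)


def density_at(times: np.ndarray, events: np.ndarray, sigma: float) -> np.ndarray:
    """Sum of unit-amplitude Gaussians centered on ``events``."""
    d = np.zeros_like(times, dtype=float)
    for lo in range(0, len(events), 512):
        chunk = events[lo : lo + 512]
        d += np.exp(-((times[:, None] - chunk[None]) ** 2) / (2.0 * sigma**2)).sum(axis=1)
    return d


def kde_clusters(
    event_times: Sequence[float],
    config: KdeClusterConfig = KdeClusterConfig(),
    tags: Sequence[str] | None = None,
    grid_step: float = 0.25,
) -> ClusterResult:
    """Cluster headfix events by thresholded 1-D kernel density.

    A break is placed between two consecutive events whenever the summed
    density drops below ``threshold_fraction`` x the isolated-peak
    amplitude (1.0 for unit Gaussians) somewhere in the gap.  With
    ``tags`` given, the number of distinct mice per cluster is reported —
    headfix clusters frequently involve several mice.
    """
    times = np.asarray(event_times, dtype=float)
    if tags is not None and len(tags) != len(times):
        raise ValueError("tags must match event_times in length")
    if times.size == 0:
        return ClusterResult(labels=np.empty(0, int), sizes=np.empty(0, int), mouse_counts=None)
    order = np.argsort(times, kind="stable")
    st = times[order]
    threshold = config.threshold_fraction  # isolated peak amplitude is 1.0
    far = 6.0 * config.sigma  # beyond this, contributions are negligible

    labels_sorted = np.zeros(len(st), dtype=int)
    current = 0
    for i in range(1, len(st)):
        gap = st[i] - st[i - 1]
        if gap <= 0:
            labels_sorted[i] = current
            continue
        if gap > 2.0 * far:
            broken = True
        else:
            grid = np.arange(st[i - 1], st[i] + grid_step / 2, grid_step)
            lo = np.searchsorted(st, grid[0] - far)
            hi = np.searchsorted(st, grid[-1] + far)
            d = density_at(grid, st[lo:hi], config.sigma)
            broken = bool(d.min() < threshold)
        if broken:
            current += 1
        labels_sorted[i] = current

    labels = np.empty(len(st), dtype=int)
    labels[order] = labels_sorted
    sizes = np.bincount(labels_sorted)
    mouse_counts = None
    if tags is not None:
        tag_arr = np.asarray(tags, dtype=object)[order]
        mouse_counts = np.array(
            [len(set(tag_arr[labels_sorted == k])) for k in range(current + 1)]
        )
    return ClusterResult(labels=labels, sizes=sizes, mouse_counts=mouse_counts)


# --------------------------------------------------------------------------
# Signal-detection d'


@dataclass(frozen=True)
class DPrimeResult:
    """Sensitivity index z(hit) - z(false alarm); 0 = no discrimination."""

    hit_rate: float
    false_alarm_rate: float
    dprime: float
    n_go: int
    n_nogo: int


def dprime(outcomes: Sequence[int]) -> DPrimeResult:
    """d' from trial outcome codes.

    Early-lick failures (-4 go, -3 no-go) reflect stimulus detection and
    are disregarded; hit rate = +2 / (+2 + -2) and false-alarm rate =
    -1 / (-1 + +1).  Extreme rates are clamped to [1/(2n), 1 - 1/(2n)]
    before the normal quantile so d' stays finite.
    """
    counts = {c: 0 for c in (2, -2, -4, 1, -1, -3)}
    for code in outcomes:
        if code not in counts:
            raise ValueError(f"unknown outcome code {code}")
        counts[code] += 1
    n_go = counts[2] + counts[-2]
    n_nogo = counts[1] + counts[-1]
    if n_go == 0 or n_nogo == 0:
        raise ValueError("need at least one scored go and one scored no-go trial")

    def clamp(rate: float, n: int) -> float:
        lo = 1.0 / (2.0 * n)
        return min(max(rate, lo), 1.0 - lo)

    hit = clamp(counts[2] / n_go, n_go)
    fa = clamp(counts[-1] / n_nogo, n_nogo)
    d = float(_stats.norm.ppf(hit) - _stats.norm.ppf(fa))
    return DPrimeResult(hit_rate=hit, false_alarm_rate=fa, dprime=d, n_go=n_go, n_nogo=n_nogo)


# --------------------------------------------------------------------------
# Participation tables

_COUNT_KINDS = ("entries", "licks", "headfixes", "time_fixed")


def daily_counts(
    store: EventStore,
    kind: str,
    day0: float = 0.0,
    sessions: Sequence[HeadfixSession] | None = None,
) -> pd.DataFrame:
    """Per-mouse per-day counts (or seconds for ``time_fixed``).

    Days are relative to ``day0``, the starting day of the loose
    head-fixing protocol.  ``headfixes``/``time_fixed`` are computed from
    parsed sessions (``fixed`` sessions only); pass ``sessions`` to reuse
    an existing parse.
    """
    if kind not in _COUNT_KINDS:
        raise ValueError(f"unknown kind {kind!r}; expected one of {_COUNT_KINDS}")
    rows: list[dict] = []
    if kind in ("entries", "licks"):
        event = "entry" if kind == "entries" else "lick"
        for rec in store.by_event(event):
            rows.append({"tag": rec.tag, "day": int(rec.timestamp // SECONDS_PER_DAY - day0), "value": 1.0})
    else:
        if sessions is None:
            sessions = parse_sessions(store)
        for s in sessions:
            if not s.fixed:
                continue
            value = s.duration if kind == "time_fixed" else 1.0
            rows.append({"tag": s.tag, "day": int(s.start // SECONDS_PER_DAY - day0), "value": value})
    if not rows:
        return pd.DataFrame(columns=["tag", "day", "value"]).astype({"day": int, "value": float})
    df = pd.DataFrame(rows)
    return df.groupby(["tag", "day"], as_index=False)["value"].sum()


# --------------------------------------------------------------------------
# Interval structure


@dataclass
class IntervalStats:
    """Same-mouse and cross-mouse inter-headfix interval samples.

    ``same_mouse[tag]`` are intervals between that mouse's consecutive
    sessions; ``cross_mouse`` holds, for each session start, the time to
    the next session started by a *different* mouse.  Group summaries are
    averages of per-mouse medians (same) and the pooled median (cross).
    """

    same_mouse: dict[str, np.ndarray]
    cross_mouse: np.ndarray
    same_medians: dict[str, float]
    avg_same_median: float
    cross_median: float


def interval_stats(
    sessions: Sequence[HeadfixSession],
    definition: Literal["gap", "start_to_start"] = "gap",
) -> IntervalStats:
    """Inter-headfix interval structure within and between mice.

    ``definition='gap'`` (default) measures from a session's end (release)
    to the same mouse's next session start — the re-fixation latency;
    ``'start_to_start'`` measures between consecutive session starts.
    Cross-mouse intervals are always start-to-next-different-tag-start.
    """
    if len(sessions) < 2:
        return IntervalStats({}, np.empty(0), {}, float("nan"), float("nan"))
    ordered = sorted(sessions, key=lambda s: s.start)
    same: dict[str, list[float]] = {}
    by_tag: dict[str, list[HeadfixSession]] = {}
    for s in ordered:
        by_tag.setdefault(s.tag, []).append(s)
    for tag, ss in by_tag.items():
        vals = []
        for a, b in zip(ss, ss[1:]):
            vals.append(b.start - (a.end if definition == "gap" else a.start))
        if vals:
            same[tag] = np.asarray(vals)

    starts = np.array([s.start for s in ordered])
    tags = [s.tag for s in ordered]
    cross: list[float] = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            if tags[j] != tags[i]:
                cross.append(starts[j] - starts[i])
                break
    cross_arr = np.asarray(cross)
    medians = {tag: float(np.median(v)) for tag, v in same.items()}
    avg_same = float(np.mean(list(medians.values()))) if medians else float("nan")
    cross_med = float(np.median(cross_arr)) if cross_arr.size else float("nan")
    return IntervalStats(
        same_mouse={t: v for t, v in same.items()},
        cross_mouse=cross_arr,
        same_medians=medians,
        avg_same_median=avg_same,
        cross_median=cross_med,
    )


def day_night_fraction(
    sessions: Sequence[HeadfixSession],
    lights_on: float = LIGHTS_ON,
    lights_off: float = LIGHTS_OFF,
) -> float:
    """Fraction of session starts in the dark phase (default 19:00-07:00)."""
    if not sessions:
        return float("nan")
    night = sum(_is_night(s.start, lights_on, lights_off) for s in sessions)
    return night / len(sessions)


def day_night_success(
    sessions: Sequence[HeadfixSession],
    min_days: int = 10,
    lights_on: float = LIGHTS_ON,
    lights_off: float = LIGHTS_OFF,
) -> pd.DataFrame:
    """Per-mouse day/night go-task success ratio with a one-sample t-test.

    For each mouse and day, the go success rate (+2 over all go outcomes)
    is computed separately for light and dark phases; days lacking go
    trials in either phase are excluded.  Mice with fewer than ``min_days``
    qualifying days are excluded.  The per-mouse t-test compares the daily
    day/night ratios against 1 (no diurnal preference).
    """
    rows: dict[tuple[str, int, bool], list[int]] = {}
    for s in sessions:
        day = int(s.start // SECONDS_PER_DAY)
        night = _is_night(s.start, lights_on, lights_off)
        for t in s.trials:
            if t.cue_kind == "go" and t.outcome is not None:
                rows.setdefault((s.tag, day, night), []).append(t.outcome)

    def rate(codes: list[int]) -> float:
        return sum(c == 2 for c in codes) / len(codes)

    out = []
    tags = sorted({k[0] for k in rows})
    for tag in tags:
        ratios = []
        days = sorted({k[1] for k in rows if k[0] == tag})
        for day in days:
            day_codes = rows.get((tag, day, False))
            night_codes = rows.get((tag, day, True))
            if not day_codes or not night_codes:
                continue
            nr = rate(night_codes)
            if nr == 0:
                continue
            ratios.append(rate(day_codes) / nr)
        if len(ratios) < min_days:
            continue
        arr = np.asarray(ratios)
        if np.allclose(arr, arr[0]):
            t, p = (0.0, 1.0) if np.isclose(arr[0], 1.0) else (np.inf, 0.0)
        else:
            t, p = _stats.ttest_1samp(arr, 1.0)
        out.append(
            {"tag": tag, "n_days": len(ratios), "mean_ratio": arr.mean(), "t": float(t), "p": float(p)}
        )
    return pd.DataFrame(out, columns=["tag", "n_days", "mean_ratio", "t", "p"])


# --------------------------------------------------------------------------
# Per-mouse summary table

_SUMMARY_COLUMNS = [
    "tag",
    "group",
    "days_protocol",
    "days_headfix",
    "total_headfixes",
    "total_hours",
    "headfixes_per_day",
    "minutes_per_day",
    "go_success_last5",
    "daily_trials_5day",
]


def table_summary(
    store: EventStore,
    good_performer_min_minutes: float = 20.0,
    sessions: Sequence[HeadfixSession] | None = None,
    group: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-mouse head-fixation summary statistics.

    Reproduces the canonical summary-table semantics: days under protocol
    (span of the mouse's events), days with head-fixation, total
    head-fixes, total hours head-fixed, head-fixes and minutes per
    day-with-headfixation, go success rate over the last 5 days having
    headfixed go trials (+2 over all go outcomes, %), and the daily trial
    average over those 5 days (all outcomes).  Mice with under
    ``good_performer_min_minutes`` of total head-fixation are excluded as
    poor performers.
    """
    if sessions is None:
        sessions = parse_sessions(store)
    rows = []
    for tag in store.tags():
        ev = store.by_tag(tag)
        first_day = int(ev[0].timestamp // SECONDS_PER_DAY)
        last_day = int(ev[-1].timestamp // SECONDS_PER_DAY)
        fixed = [s for s in sessions if s.tag == tag and s.fixed]
        total_minutes = sum(s.duration for s in fixed) / 60.0
        if total_minutes < good_performer_min_minutes:
            continue
        days_fix = sorted({int(s.start // SECONDS_PER_DAY) for s in fixed})
        n_days_fix = len(days_fix)
        per_day_trials: dict[int, int] = {}
        per_day_go: dict[int, list[int]] = {}
        for s in fixed:
            day = int(s.start // SECONDS_PER_DAY)
            per_day_trials[day] = per_day_trials.get(day, 0) + len(s.outcomes())
            go = [t.outcome for t in s.trials if t.cue_kind == "go" and t.outcome is not None]
            if go:
                per_day_go.setdefault(day, []).extend(go)
        go_days = sorted(per_day_go)[-5:]
        if go_days:
            codes = [c for d in go_days for c in per_day_go[d]]
            success = 100.0 * sum(c == 2 for c in codes) / len(codes)
            trials5 = np.mean([per_day_trials.get(d, 0) for d in go_days])
        else:
            success, trials5 = float("nan"), float("nan")
        rows.append(
            {
                "tag": tag,
                "group": (group or {}).get(tag, 0),
                "days_protocol": last_day - first_day + 1,
                "days_headfix": n_days_fix,
                "total_headfixes": len(fixed),
                "total_hours": sum(s.duration for s in fixed) / 3600.0,
                "headfixes_per_day": len(fixed) / n_days_fix if n_days_fix else 0.0,
                "minutes_per_day": total_minutes / n_days_fix if n_days_fix else 0.0,
                "go_success_last5": success,
                "daily_trials_5day": trials5,
            }
        )
    return pd.DataFrame(rows, columns=_SUMMARY_COLUMNS)


def aggregate_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Append AVG / STDEV / SUM rows to a per-mouse summary table.

    AVG is the arithmetic mean, STDEV the sample standard deviation
    (n - 1; empty when only one mouse), SUM the plain column sum; the
    success-rate column has no meaningful sum and is left empty there.
    """
    numeric = [c for c in _SUMMARY_COLUMNS if c not in ("tag", "group")]
    body = df[numeric].astype(float)
    avg = body.mean()
    std = body.std(ddof=1) if len(df) > 1 else pd.Series(np.nan, index=numeric)
    total = body.sum()
    total["go_success_last5"] = np.nan

    def row(label: str, values: pd.Series) -> dict:
        out = {"tag": label, "group": ""}
        out.update(values.to_dict())
        return out

    extra = pd.DataFrame([row("AVG", avg), row("STDEV", std), row("SUM", total)])
    return pd.concat([df, extra], ignore_index=True)


def load_printed_summary(sex: Literal["male", "female"] = "male") -> pd.DataFrame:
    """Load the packaged good-performer summary rows (23 males tested 24/7,
    5 females lab-trained ~7 h/day) as published for this cage system."""
    name = f"table1_{sex}.csv"
    with importlib.resources.files("mesocage.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, dtype={"tag": str})


# --------------------------------------------------------------------------
# Timing uniformity


@dataclass(frozen=True)
class AndersonResult:
    statistic: float
    critical_values: tuple[float, ...]
    significance_levels: tuple[float, ...]  # percent


def interval_uniformity(
    start_times: Sequence[float],
    dist: Literal["norm", "uniform"] = "norm",
) -> AndersonResult:
    """Anderson-Darling test of session times-of-day against a reference.

    ``norm`` delegates to the standard routine (estimated mean/SD);
    ``uniform`` uses the fully-specified-distribution A^2 statistic on the
    probability-integral transform of clock hours.  Clustered headfixing
    produces statistics far above the 1% critical value.
    """
    times = np.asarray(start_times, dtype=float)
    if times.size < 8:
        raise ValueError("need at least 8 events")
    hours = (times / 3600.0) % 24.0
    if dist == "norm":
        import warnings

        with warnings.catch_warnings():
            # keep the critical-value interface across scipy versions
            warnings.simplefilter("ignore", FutureWarning)
            res = _stats.anderson(hours, dist="norm")
        return AndersonResult(
            statistic=float(res.statistic),
            critical_values=tuple(float(c) for c in res.critical_values),
            significance_levels=tuple(float(s) for s in res.significance_level),
        )
    if dist == "uniform":
        u = np.sort(hours / 24.0)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        n = len(u)
        i = np.arange(1, n + 1)
        a2 = -n - np.mean((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1])))
        # case-0 (fully specified distribution) critical values
        return AndersonResult(
            statistic=float(a2),
            critical_values=(1.610, 1.933, 2.492, 3.070, 3.857),
            significance_levels=(15.0, 10.0, 5.0, 2.5, 1.0),
        )
    raise ValueError(f"unknown dist {dist!r}")
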