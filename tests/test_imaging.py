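"""Imaging pipeline: registration, dF/F, correction, maps, gradients."""

import numpy as np
import pytest

from mesocage.imaging import (
    ATLAS,
    ImagingStack,
    behavior_gradient,
    bin_spatial,
    brain_behavior_map,
    compute_dff,
    global_signal_regress,
    group_brain_behavior,
    hemodynamic_correct,
    max_bin_montage,
    register_frames,
    seed_pixel_map,
    trial_average,
)


def _stack(green, blue=None, frame_rate=30.0):
    green = np.asarray(green, float)
    blue = green.copy() if blue is None else np.asarray(blue, float)
    times = np.arange(green.shape[0]) / frame_rate
    return ImagingStack(green, blue, times, frame_rate=frame_rate)


# ------------------------------------------------------------- registration


def test_register_identical_frames_zero_shifts():
    rng = np.random.default_rng(0)
    frame = rng.uniform(50, 150, size=(64, 64))
    stack = _stack(np.stack([frame] * 5))
    _, shifts = register_frames(stack)
    assert np.all(shifts == 0)


@pytest.mark.parametrize("dy, dx", [(3, -2), (-5, 4), (8, 8), (-8, -8)])
def test_register_recovers_constructed_integer_shift(dy, dx):
    rng = np.random.default_rng(1)
    ref = rng.uniform(50, 150, size=(64, 64))
    moved = np.roll(ref, (dy, dx), axis=(0, 1))
    stack = _stack(np.stack([ref, moved]))
    registered, shifts = register_frames(stack)
    # the estimated correction undoes the constructed translation exactly
    assert tuple(np.abs(shifts[1]).astype(int)) == (abs(dy), abs(dx))
    interior = (slice(12, 52), slice(12, 52))
    np.testing.assert_allclose(registered.green[1][interior], ref[interior], atol=1e-8)


def test_register_exact_under_noise():
    """Integer shift recovery survives additive noise at SNR ~ 5."""
    rng = np.random.default_rng(2)
    ref = rng.uniform(50, 150, size=(64, 64))
    sd = ref.std() / 5.0
    moved = np.roll(ref, (4, -3), axis=(0, 1)) + rng.normal(0, sd, ref.shape)
    stack = _stack(np.stack([ref, moved]))
    _, shifts = register_frames(stack)
    assert tuple(np.abs(shifts[1]).astype(int)) == (4, 3)


def test_register_warns_on_blank_frame():
    stack = _stack(np.stack([np.ones((16, 16)), np.zeros((16, 16))]))
    with pytest.warns(UserWarning, match="zero"):
        _, shifts = register_frames(stack)
    assert np.all(shifts[1] == 0)


def test_register_applies_same_shift_to_blue_channel():
    rng = np.random.default_rng(3)
    ref = rng.uniform(50, 150, size=(32, 32))
    moved = np.roll(ref, (2, 1), axis=(0, 1))
    stack = _stack(np.stack([ref, moved]), blue=np.stack([ref, moved]) * 0.5)
    registered, _ = register_frames(stack)
    np.testing.assert_allclose(registered.blue[1], registered.green[1] * 0.5, atol=1e-8)


# ----------------------------------------------------------------- dF/F


def test_dff_constant_movie_is_zero():
    stack = _stack(np.full((10, 8, 8), 100.0))
    dff = compute_dff(stack)
    np.testing.assert_allclose(dff.green_dff, 0.0, atol=1e-12)


def test_dff_single_transient_amplitude():
    frames = np.full((10, 4, 4), 100.0)
    frames[5, 2, 2] = 105.0
    stack = _stack(frames)
    dff = compute_dff(stack, f0_method="window", baseline_frames=slice(0, 4))
    assert dff.green_dff[5, 2, 2] == pytest.approx(0.05)
    assert dff.green_dff[0, 2, 2] == pytest.approx(0.0)


def test_dff_masks_zero_baseline_pixels():
    frames = np.full((6, 4, 4), 100.0)
    frames[:, 0, 0] = 0.0
    dff = compute_dff(_stack(frames))
    assert np.isnan(dff.green_dff[:, 0, 0]).all()
    assert np.isfinite(dff.green_dff[:, 1, 1]).all()


# ----------------------------------------------------------- hemodynamics


def test_correction_is_identity_when_blue_flat():
    frames = np.full((10, 4, 4), 100.0)
    frames[5] = 104.0
    stack = _stack(frames, blue=np.full((10, 4, 4), 80.0))
    dff = hemodynamic_correct(compute_dff(stack, "window", baseline_frames=slice(0, 4)))
    np.testing.assert_allclose(dff.corrected, dff.green_dff, atol=1e-12)


def test_correction_subtracts_elementwise():
    g = np.zeros((2, 1, 1))
    b = np.zeros((2, 1, 1))
    g[1] = 0.05
    b[1] = 0.01
    from mesocage.imaging import DffStack

    dff = DffStack(green_dff=g, blue_dff=b, times=np.arange(2.0), f0_method="mean",
                   f0_green=np.ones((1, 1)), f0_blue=np.ones((1, 1)))
    out = hemodynamic_correct(dff)
    assert out.corrected[1, 0, 0] == pytest.approx(0.04)


def test_correction_cancels_shared_artifact_noiseless(go_trials):
    """With zero sensor noise, corrected dF/F equals the neural truth to
    second order in the (small) artifact."""
    from mesocage.mouse_sim import SyntheticMovieConfig, simulate_movie

    cfg = SyntheticMovieConfig(noise_sd=0.0, artifact_gain=0.15)
    stack, truth = simulate_movie(go_trials, cfg, np.random.default_rng(0))
    dff = hemodynamic_correct(compute_dff(stack))
    expected = (1 + truth.neural) / (1 + truth.neural).mean(axis=0)[None] - 1
    assert np.nanmax(np.abs(dff.corrected - expected)) < 1e-3


def test_correction_cancels_shared_artifact_with_noise(synthetic_movie):
    """Per-pixel RMS deviation from neural truth stays under 3x noise SD."""
    stack, truth = synthetic_movie
    dff = hemodynamic_correct(compute_dff(stack))
    expected = (1 + truth.neural) / (1 + truth.neural).mean(axis=0)[None] - 1
    resid = dff.corrected - expected
    rms = np.sqrt(np.nanmean(resid**2, axis=0))
    noise_sd = np.sqrt(2) * 0.002  # two channels of additive sensor noise
    assert rms.max() < 3 * noise_sd
    assert dff.blue_green_ratio < 0.35


# ---------------------------------------------------------------- binning


def test_bin_spatial_256_to_64_preserves_mean():
    rng = np.random.default_rng(0)
    frames = rng.uniform(0, 190, size=(3, 256, 256))
    out = bin_spatial(frames, 4)
    assert out.shape == (3, 64, 64)
    np.testing.assert_allclose(out.mean(), frames.mean())


def test_bin_spatial_checkerboard_uniform():
    tile = np.array([[1.0, 0.0], [0.0, 1.0]])
    board = np.tile(tile, (4, 4))
    out = bin_spatial(board, 2)
    np.testing.assert_allclose(out, 0.5)


def test_bin_spatial_rejects_nondivisible():
    with pytest.raises(ValueError, match="divisible"):
        bin_spatial(np.zeros((2, 10, 10)), 3)


# ---------------------------------------------------------- trial averaging


def test_trial_average_single_trial_is_identity(go_trials, synthetic_movie):
    stack, _ = synthetic_movie
    dff = hemodynamic_correct(compute_dff(stack))
    ta = trial_average(dff.corrected, stack.times, go_trials[:1], window=(-2.0, 3.0))
    assert ta.n_trials == 1
    k = int(round((go_trials[0].cue_time - stack.times[0]) * 30))
    np.testing.assert_allclose(ta.mean, dff.corrected[k - 60 : k + 91], atol=1e-12)


def test_trial_average_opposite_signals_cancel():
    from mesocage.eventlog import Trial

    T = 400
    data = np.zeros((T, 4, 4))
    data[90:120] = 1.0
    data[290:320] = -1.0
    times = np.arange(T) / 30.0
    trials = [
        Trial(cue_time=3.0, cue_kind="go", withhold_duration=1, delay=0.9, outcome=2),
        Trial(cue_time=29.0 / 3, cue_kind="go", withhold_duration=1, delay=0.9, outcome=2),
    ]
    ta = trial_average(data, times, trials, window=(-1.0, 2.0))
    np.testing.assert_allclose(ta.mean, 0.0, atol=1e-12)


def test_trial_average_movement_filter_uses_truth(go_trials, synthetic_movie):
    """The low-movement filter drops exactly the built-in movement trials."""
    from mesocage.imaging import BehaviorTrace

    stack, truth = synthetic_movie
    dff = hemodynamic_correct(compute_dff(stack))
    behavior = BehaviorTrace(values={"hindlimb": truth.behavior["hindlimb"]}, scale_min=0, scale_max=1)
    ta = trial_average(
        dff.corrected,
        stack.times,
        go_trials,
        window=(-2.0, 3.0),
        behavior=behavior,
        behavior_roi="hindlimb",
        movement_threshold_sd=0.4,
    )
    expected = [i for i, m in enumerate(truth.precue_movement) if m == 0.0]
    assert ta.used_trials == expected


def test_trial_average_requires_qualifying_trials(go_trials, synthetic_movie):
    stack, _ = synthetic_movie
    with pytest.raises(ValueError, match="qualifying"):
        trial_average(np.zeros((10, 4, 4)), stack.times[:10], go_trials, window=(-2.0, 3.0))


# ----------------------------------------------------------------- montage


def test_montage_constant_stack():
    out = max_bin_montage(np.full((30, 4, 4), 2.0), 0.5)
    assert out.shape == (2, 4, 4)
    np.testing.assert_allclose(out, 2.0)


def test_montage_spike_lands_in_one_bin():
    frames = np.zeros((60, 2, 2))
    frames[40, 1, 1] = 5.0
    out = max_bin_montage(frames, 0.5)
    assert out[2, 1, 1] == 5.0
    assert out[[0, 1, 3], 1, 1].max() == 0.0


def test_montage_ramp_takes_bin_maximum():
    T = 90
    frames = np.arange(T, dtype=float)[:, None, None] * np.ones((1, 2, 2))
    out = max_bin_montage(frames, 0.5)
    np.testing.assert_allclose(out[:, 0, 0], [14.0, 29.0, 44.0, 59.0, 74.0, 89.0])


# -------------------------------------------------------------- seed maps


def _random_movie(T=300, h=8, w=8, seed=0):
    rng = np.random.default_rng(seed)
    return rng.standard_normal((T, h, w))


def test_seed_map_self_correlation_is_one():
    data = _random_movie()
    r = seed_pixel_map(data, (3, 3))
    assert r[3, 3] == pytest.approx(1.0)


def test_seed_map_shared_time_course_is_one():
    data = _random_movie()
    data[:, 5, 5] = data[:, 3, 3]
    r = seed_pixel_map(data, (3, 3))
    assert r[5, 5] == pytest.approx(1.0)


def test_seed_map_symmetric_in_seed_choice():
    data = _random_movie(seed=4)
    ra = seed_pixel_map(data, (2, 6))
    rb = seed_pixel_map(data, (5, 1))
    assert ra[5, 1] == pytest.approx(rb[2, 6], abs=1e-12)


def test_gsr_removes_injected_global_component():
    rng = np.random.default_rng(5)
    T = 3000
    data = rng.standard_normal((T, 6, 6))
    g = rng.standard_normal(T)
    data += 2.0 * g[:, None, None]
    r = seed_pixel_map(data, (0, 0), use_gsr=True)
    off_seed = np.delete(r.ravel(), 0)
    assert np.abs(off_seed).max() < 0.1


def test_gsr_idempotent():
    data = _random_movie(seed=6) + 3.0
    once = global_signal_regress(data)
    twice = global_signal_regress(once)
    np.testing.assert_allclose(once, twice, atol=1e-10)


def test_seed_map_rejects_zero_variance_seed():
    data = _random_movie()
    data[:, 0, 0] = 1.0
    with pytest.raises(ValueError, match="variance"):
        seed_pixel_map(data, (0, 0))


# ------------------------------------------------------- behavior gradients


def test_behavior_gradient_static_video_zero():
    trace = behavior_gradient({"leg": np.ones((20, 4, 4))})
    np.testing.assert_allclose(trace.values["leg"], 0.0)


def test_behavior_gradient_step_change_single_sample():
    video = np.zeros((10, 4, 4))
    video[5:] = 1.0
    trace = behavior_gradient({"leg": video})
    vals = trace.values["leg"]
    assert vals[5] == pytest.approx(1.0)
    assert np.delete(vals, 5).max() == 0.0


def test_behavior_gradient_joint_scaling_max_is_one():
    rng = np.random.default_rng(0)
    quiet = rng.uniform(0, 0.1, size=(30, 4, 4))
    busy = rng.uniform(0, 5.0, size=(30, 4, 4))
    trace = behavior_gradient({"quiet": quiet, "busy": busy})
    all_vals = np.concatenate([trace.values["quiet"], trace.values["busy"]])
    assert all_vals.max() == pytest.approx(1.0)
    assert trace.values["quiet"].max() < trace.values["busy"].max()


# ------------------------------------------------------ brain-behavior maps


def test_brain_behavior_map_exact_pixel_match():
    data = _random_movie(seed=7)
    r = brain_behavior_map(data, data[:, 4, 4])
    assert r[4, 4] == pytest.approx(1.0)


def test_brain_behavior_map_independent_noise_small():
    data = _random_movie(T=2000, seed=8)
    rng = np.random.default_rng(9)
    r = brain_behavior_map(data, rng.standard_normal(2000))
    assert np.abs(r).max() < 3 * 2 / np.sqrt(2000)


def test_brain_behavior_map_peaks_in_driven_region(go_trials, synthetic_movie):
    """A licking-locked trace correlates most strongly inside ALM."""
    stack, truth = synthetic_movie
    dff = hemodynamic_correct(compute_dff(stack))
    r = brain_behavior_map(np.nan_to_num(dff.corrected), truth.behavior["tongue"])
    boxes = ATLAS["ALM"].pixel_boxes(stack.shape, stack.mm_per_pixel, stack.bregma)
    peak = np.unravel_index(np.argmax(r), r.shape)
    inside = any(r0 - 2 <= peak[0] < r1 + 2 and c0 - 2 <= peak[1] < c1 + 2
                 for r0, r1, c0, c1 in boxes)
    assert inside, (peak, boxes)


def test_brain_behavior_map_length_mismatch():
    with pytest.raises(ValueError, match="length"):
        brain_behavior_map(np.zeros((10, 2, 2)), np.zeros(9))


# ------------------------------------------------------------ group analysis


def test_group_shared_template_not_significant():
    rng = np.random.default_rng(0)
    template = np.sin(np.linspace(0, 3 * np.pi, 90))
    calcium = {f"m{i}": np.tile(template, (25, 1)) for i in range(5)}
    behavior = {f"m{i}": np.tile(template, (25, 1)) for i in range(5)}
    res = group_brain_behavior(calcium, behavior)
    np.testing.assert_allclose(res.correct_pair_corr, 1.0, atol=1e-9)
    assert res.wilcoxon_p > 0.05


def test_group_mouse_specific_templates_significant():
    """Matched per-mouse dynamics beat cross-mouse shuffled pairings."""
    rng = np.random.default_rng(1)
    F, n_tr, n_mice = 90, 25, 13
    calcium, behavior = {}, {}
    t = np.linspace(0, 1, F)
    for i in range(n_mice):
        template = np.sin(2 * np.pi * (1 + 0.35 * i) * t)
        calcium[f"m{i}"] = template + 0.2 * rng.standard_normal((n_tr, F))
        behavior[f"m{i}"] = np.tile(template, (n_tr, 1)) + 0.05 * rng.standard_normal((n_tr, F))
    res = group_brain_behavior(calcium, behavior)
    assert res.correct_pair_corr.mean() > res.shuffled_pair_corr.mean()
    assert res.wilcoxon_p < 0.05


def test_group_excludes_low_trial_mice_and_needs_three():
    rng = np.random.default_rng(2)
    trace = rng.standard_normal((25, 50))
    few = rng.standard_normal((5, 50))
    with pytest.raises(ValueError, match="3 mice"):
        group_brain_behavior({"a": trace, "b": few, "c": few}, {"a": trace, "b": few, "c": few})
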