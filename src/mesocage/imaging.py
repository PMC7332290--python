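"""Mesoscale widefield GCaMP imaging pipeline.

Two channels are acquired through a triple-band filter on one RGB sensor:
green epifluorescence (the calcium signal) and 440 nm reflected blue light,
near the hemoglobin isosbestic point, which sees hemodynamic and movement
artifacts but not calcium.  The pipeline registers frames by
cross-correlation, computes per-pixel dF/F0 in both channels, subtracts the
equally-scaled blue-reflectance dF/F0 from the green to cancel the shared
multiplicative artifact, and supports trial-aligned averaging, max-value
montages, seed-pixel correlation maps (with optional global signal
regression), behavioral-video movement gradients, and brain-behavior
correlation at zero lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from .eventlog import Trial

__all__ = [
    "ImagingStack",
    "DffStack",
    "RoiSpec",
    "ATLAS",
    "BehaviorTrace",
    "TrialAverage",
    "GroupBrainBehavior",
    "register_frames",
    "compute_dff",
    "hemodynamic_correct",
    "bin_spatial",
    "trial_average",
    "max_bin_montage",
    "global_signal_regress",
    "seed_pixel_map",
    "behavior_gradient",
    "brain_behavior_map",
    "group_brain_behavior",
]


@dataclass
class ImagingStack:
    """Two-channel movie: green epifluorescence + 440 nm blue reflectance.

    ``times`` is the per-frame timebase (seconds); after alignment the
    nominal frame rate is 30 Hz.  ``bregma`` is the (row, col) pixel of the
    bregma landmark used to place atlas-referenced ROIs; coordinates are
    0-based with anterior toward row 0.
    """

    green: np.ndarray  # (T, H, W)
    blue: np.ndarray  # (T, H, W)
    times: np.ndarray  # (T,)
    frame_rate: float = 30.0
    mm_per_pixel: float = 8.2 / 64.0
    bregma: tuple[int, int] = (24, 32)

    def __post_init__(self) -> None:
        self.green = np.asarray(self.green, dtype=float)
        self.blue = np.asarray(self.blue, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.green.shape != self.blue.shape:
            raise ValueError("green and blue channels must share a shape")
        if self.green.shape[0] != len(self.times):
            raise ValueError("timebase length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.green.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.green.shape[1], self.green.shape[2]

    def validate_levels(self, limit: float = 190 / 256) -> bool:
        """Check the acquisition headroom convention (values < 190/256 of
        range); returns the verdict rather than raising."""
        full = max(self.green.max(), self.blue.max())
        return bool(full < limit * 256)

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, np.stack([self.green, self.blue], axis=1).astype("float32"))

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("green", data=self.green)
            fh.create_dataset("blue", data=self.blue)
            fh.create_dataset("times", data=self.times)
            fh.attrs["frame_rate"] = self.frame_rate
            fh.attrs["mm_per_pixel"] = self.mm_per_pixel
            fh.attrs["bregma"] = self.bregma


@dataclass
class DffStack:
    """Per-pixel dF/F0 for both channels plus the corrected signal.

    ``corrected`` (green dF/F minus blue dF/F, elementwise) is filled by
    :func:`hemodynamic_correct`; ``f0_method`` records how the baseline was
    defined since different baselines change the scale of dF/F.
    """

    green_dff: np.ndarray
    blue_dff: np.ndarray
    times: np.ndarray
    f0_method: str
    f0_green: np.ndarray
    f0_blue: np.ndarray
    mm_per_pixel: float = 8.2 / 64.0
    bregma: tuple[int, int] = (24, 32)
    frame_rate: float = 30.0
    corrected: np.ndarray | None = None
    blue_green_ratio: float | None = None


@dataclass(frozen=True)
class RoiSpec:
    """Square cortical ROI in bregma-referenced millimetres.

    ``ap_mm`` is positive anterior of bregma, ``ml_mm`` positive lateral;
    ``side='bilateral'`` yields mirrored left/right boxes.  The default
    extent matches the 0.7 x 0.7 mm convention used for region-averaged
    decoding traces.
    """

    name: str
    ap_mm: float
    ml_mm: float
    extent_mm: float = 0.7
    side: str = "bilateral"  # left | right | bilateral

    def pixel_boxes(
        self,
        shape: tuple[int, int],
        mm_per_pixel: float,
        bregma: tuple[int, int],
    ) -> list[tuple[int, int, int, int]]:
        """(r0, r1, c0, c1) half-open pixel boxes, one per hemisphere."""
        h, w = shape
        half = max(1, int(round(self.extent_mm / mm_per_pixel / 2)))
        row = bregma[0] - self.ap_mm / mm_per_pixel
        boxes = []
        sides = {"left": [-1], "right": [+1], "bilateral": [-1, +1]}[self.side]
        for s in sides:
            col = bregma[1] + s * self.ml_mm / mm_per_pixel
            r0, r1 = int(round(row)) - half, int(round(row)) + half + 1
            c0, c1 = int(round(col)) - half, int(round(col)) + half + 1
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                raise ValueError(f"ROI {self.name} box outside image bounds")
            boxes.append((r0, r1, c0, c1))
        return boxes


#: Default 8-region dorsal-cortex parcellation (bilateral pairs averaged in
#: decoding): anterior-lateral motor, secondary/primary motor, fore/hindlimb
#: somatosensory, barrel, retrosplenial, and primary visual cortex.
#: Centers approximate the Allen CCF dorsal projection.
ATLAS: dict[str, RoiSpec] = {
    "ALM": RoiSpec("ALM", 2.5, 1.5),
    "M2": RoiSpec("M2", 1.5, 0.75),
    "M1": RoiSpec("M1", 1.0, 1.6),
    "FL": RoiSpec("FL", 0.2, 2.2),
    "HL": RoiSpec("HL", -0.6, 1.7),
    "BC": RoiSpec("BC", -1.2, 3.2),
    "RS": RoiSpec("RS", -2.8, 0.6),
    "V1": RoiSpec("V1", -3.6, 2.5),
}


def register_frames(
    stack: ImagingStack,
    reference: int = 0,
    upsample_factor: int = 1,
) -> tuple[ImagingStack, np.ndarray]:
    """Align frames to a reference frame by cross-correlation.

    Shifts are estimated on the green channel via FFT cross-correlation
    (integer-pixel by default, subpixel with ``upsample_factor > 1``) and
    applied consistently to both channels.  Returns the shifted stack and
    the (T, 2) array of applied (row, col) shifts.
    """
    from scipy.ndimage import shift as nd_shift
    from skimage.registration import phase_cross_correlation

    if stack.n_frames < 2:
        raise ValueError("need at least two frames to register")
    ref = stack.green[reference]
    shifts = np.zeros((stack.n_frames, 2))
    green = np.empty_like(stack.green)
    blue = np.empty_like(stack.blue)
    for t in range(stack.n_frames):
        frame = stack.green[t]
        if not np.any(frame):
            warnings.warn(f"frame {t} is all zeros; assuming zero shift")
            sh = np.zeros(2)
        elif t == reference:
            sh = np.zeros(2)
        else:
            sh, _, _ = phase_cross_correlation(
                ref, frame, upsample_factor=upsample_factor, normalization=None
            )
        shifts[t] = sh
        if np.all(sh == 0):
            green[t] = frame
            blue[t] = stack.blue[t]
        else:
            green[t] = nd_shift(frame, sh, order=1, mode="nearest")
            blue[t] = nd_shift(stack.blue[t], sh, order=1, mode="nearest")
    out = ImagingStack(
        green,
        blue,
        stack.times,
        frame_rate=stack.frame_rate,
        mm_per_pixel=stack.mm_per_pixel,
        bregma=stack.bregma,
    )
    return out, shifts


def compute_dff(
    stack: ImagingStack,
    f0_method: str = "mean",
    percentile: float = 10.0,
    baseline_frames: slice | None = None,
) -> DffStack:
    """Per-pixel (F - F0)/F0 for both channels.

    F0 choices: ``mean`` (per-pixel mean over the recording, the default),
    ``percentile`` (a low percentile, robust to dense transients), or
    ``window`` (mean over ``baseline_frames``, e.g. a pre-trial period).
    Pixels with F0 <= 0 are masked to NaN rather than raising.
    """

    def f0_of(channel: np.ndarray) -> np.ndarray:
        if f0_method == "mean":
            return channel.mean(axis=0)
        if f0_method == "percentile":
            return np.percentile(channel, percentile, axis=0)
        if f0_method == "window":
            if baseline_frames is None:
                raise ValueError("f0_method='window' needs baseline_frames")
            return channel[baseline_frames].mean(axis=0)
        raise ValueError(f"unknown f0_method: {f0_method!r}")

    def dff_of(channel: np.ndarray, f0: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            out = (channel - f0[None]) / f0[None]
        out[:, f0 <= 0] = np.nan
        return out

    f0g, f0b = f0_of(stack.green), f0_of(stack.blue)
    return DffStack(
        green_dff=dff_of(stack.green, f0g),
        blue_dff=dff_of(stack.blue, f0b),
        times=stack.times,
        f0_method=f0_method,
        f0_green=f0g,
        f0_blue=f0b,
        mm_per_pixel=stack.mm_per_pixel,
        bregma=stack.bregma,
        frame_rate=stack.frame_rate,
    )


def hemodynamic_correct(dff: DffStack) -> DffStack:
    """Subtract equally-scaled blue-reflectance dF/F from the green dF/F.

    Both channels see the same multiplicative hemodynamic/movement
    component, so unit-weight subtraction cancels it; the ratio of blue to
    green signal amplitude is reported (expected below ~20% in this
    preparation).
    """
    if dff.green_dff.shape != dff.blue_dff.shape:
        raise ValueError("channel shape mismatch")
    dff.corrected = dff.green_dff - dff.blue_dff

    def amplitude(ch: np.ndarray) -> float:
        # per-pixel temporal SD with the fast (frame-to-frame) sensor-noise
        # floor removed; the max pixel captures the localized green signal
        var = np.nanvar(ch, axis=0)
        noise = np.nanvar(np.diff(ch, axis=0), axis=0) / 2.0
        return float(np.sqrt(np.clip(var - noise, 0.0, None)).max())

    g_amp = amplitude(dff.green_dff)
    b_amp = amplitude(dff.blue_dff)
    dff.blue_green_ratio = float(b_amp / g_amp) if g_amp > 0 else float("nan")
    return dff


def bin_spatial(frames: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean spatial binning of a (T, H, W) or (H, W) array.

    The acquisition bins 256 x 256 on-camera; analysis typically bins a
    further 4x to 64 x 64.  Dimensions must divide evenly by ``factor``.
    """
    arr = np.asarray(frames, dtype=float)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    T, H, W = arr.shape
    if H % factor or W % factor:
        raise ValueError(f"image dims ({H}, {W}) not divisible by factor {factor}")
    out = arr.reshape(T, H // factor, factor, W // factor, factor).mean(axis=(2, 4))
    return out[0] if squeeze else out


@dataclass
class TrialAverage:
    """Cue-aligned average movie and per-pixel SEM over qualifying trials."""

    mean: np.ndarray  # (F, H, W)
    sem: np.ndarray
    rel_times: np.ndarray  # (F,) seconds relative to cue
    n_trials: int
    used_trials: list[int]


def trial_average(
    corrected: np.ndarray,
    times: np.ndarray,
    trials: Sequence[Trial],
    window: tuple[float, float] = (-2.5, 2.5),
    frame_rate: float = 30.0,
    outcome: int | None = None,
    behavior: "BehaviorTrace | None" = None,
    behavior_roi: str | None = None,
    movement_threshold_sd: float | None = None,
) -> TrialAverage:
    """Cue-aligned trial average of the corrected dF/F movie.

    Only trials whose full window lies inside the recording qualify.  With
    ``movement_threshold_sd`` set (e.g. 0.4), trials whose mean pre-cue
    behavioral gradient in ``behavior_roi`` exceeds that many standard
    deviations (computed across qualifying trials) are excluded — the
    low-movement filter used to stabilize pre-stimulus baselines.
    """
    times = np.asarray(times, dtype=float)
    pre, post = window
    n_pre = int(round(-pre * frame_rate))
    n_post = int(round(post * frame_rate))
    rel = np.arange(-n_pre, n_post + 1) / frame_rate

    snippets: list[np.ndarray] = []
    idxs: list[int] = []
    pre_move: list[float] = []
    for i, trial in enumerate(trials):
        if outcome is not None and trial.outcome != outcome:
            continue
        k = int(round((trial.cue_time - times[0]) * frame_rate))
        if k - n_pre < 0 or k + n_post >= corrected.shape[0]:
            continue
        snippets.append(corrected[k - n_pre : k + n_post + 1])
        idxs.append(i)
        if behavior is not None and behavior_roi is not None:
            trace = behavior.values[behavior_roi]
            pre_move.append(float(np.mean(trace[k - n_pre : k])))
    if not snippets:
        raise ValueError("no qualifying trials")

    if movement_threshold_sd is not None and pre_move:
        pm = np.asarray(pre_move)
        mu, sd = pm.mean(), pm.std()
        keep = pm <= mu + movement_threshold_sd * sd if sd > 0 else np.ones(len(pm), bool)
        snippets = [s for s, k_ in zip(snippets, keep) if k_]
        idxs = [i for i, k_ in zip(idxs, keep) if k_]
        if not snippets:
            raise ValueError("movement filter excluded all trials")

    block = np.stack(snippets)
    mean = block.mean(axis=0)
    sem = block.std(axis=0, ddof=1) / np.sqrt(block.shape[0]) if block.shape[0] > 1 else np.zeros_like(mean)
    return TrialAverage(mean=mean, sem=sem, rel_times=rel, n_trials=block.shape[0], used_trials=idxs)


def max_bin_montage(frames: np.ndarray, bin_s: float, frame_rate: float = 30.0) -> np.ndarray:
    """Pixelwise maximum within consecutive time bins (montage frames)."""
    arr = np.asarray(frames, dtype=float)
    per_bin = int(round(bin_s * frame_rate))
    if per_bin < 1:
        raise ValueError("bin shorter than a frame period")
    n_bins = arr.shape[0] // per_bin
    if n_bins == 0:
        raise ValueError("stack shorter than one bin")
    trimmed = arr[: n_bins * per_bin]
    return trimmed.reshape(n_bins, per_bin, *arr.shape[1:]).max(axis=1)


def global_signal_regress(data: np.ndarray) -> np.ndarray:
    """Regress the spatial-mean time course out of every pixel.

    Emphasizes local correlation structure in seed-pixel maps; the
    operation is idempotent up to machine precision.
    """
    T = data.shape[0]
    flat = data.reshape(T, -1)
    centered = flat - flat.mean(axis=0)
    g = centered.mean(axis=1)
    denom = float(g @ g)
    # degenerate global signal (already regressed out, or constant movie)
    if denom <= 1e-12 * max(float(centered.var()) * T, 1.0):
        return centered.reshape(data.shape)
    beta = (g @ centered) / denom
    resid = centered - np.outer(g, beta)
    return resid.reshape(data.shape)


def seed_pixel_map(
    data: np.ndarray,
    seed: tuple[int, int],
    use_gsr: bool = False,
) -> np.ndarray:
    """Pearson correlation of every pixel's time course with the seed's."""
    if data.shape[0] < 100:
        raise ValueError("need at least 100 frames for a stable map")
    if use_gsr:
        data = global_signal_regress(data)
    T = data.shape[0]
    flat = data.reshape(T, -1)
    centered = flat - flat.mean(axis=0)
    sd = centered.std(axis=0)
    seed_idx = seed[0] * data.shape[2] + seed[1]
    if sd[seed_idx] == 0:
        raise ValueError("zero-variance seed pixel")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (centered.T @ centered[:, seed_idx]) / (T * sd * sd[seed_idx])
    return r.reshape(data.shape[1:])


@dataclass
class BehaviorTrace:
    """Per-ROI movement gradients on the imaging timebase.

    Movement is the mean absolute frame-to-frame difference of each
    behavioral-video ROI pixel block, min-max scaled *jointly* across ROIs
    so the most active ROI maps to 1.
    """

    values: dict[str, np.ndarray]
    scale_min: float
    scale_max: float


def behavior_gradient(roi_blocks: Mapping[str, np.ndarray]) -> BehaviorTrace:
    """Movement traces from behavioral-video ROI pixel blocks.

    Each block is (T, h, w); the first sample of each trace is 0 so traces
    stay frame-aligned with the video.
    """
    raw: dict[str, np.ndarray] = {}
    for name, block in roi_blocks.items():
        arr = np.asarray(block, dtype=float)
        if arr.shape[0] < 2:
            raise ValueError("need at least two frames")
        grad = np.abs(np.diff(arr, axis=0)).mean(axis=(1, 2))
        raw[name] = np.concatenate([[0.0], grad])
    lo = min(v.min() for v in raw.values())
    hi = max(v.max() for v in raw.values())
    span = hi - lo
    scaled = {
        name: (v - lo) / span if span > 0 else np.zeros_like(v) for name, v in raw.items()
    }
    return BehaviorTrace(values=scaled, scale_min=float(lo), scale_max=float(hi))


def brain_behavior_map(data: np.ndarray, trace: np.ndarray) -> np.ndarray:
    """Zero-lag Pearson correlation of every pixel against a behavior trace."""
    trace = np.asarray(trace, dtype=float)
    if data.shape[0] != len(trace):
        raise ValueError("length mismatch between movie and behavior trace")
    T = data.shape[0]
    flat = data.reshape(T, -1)
    c = flat - flat.mean(axis=0)
    b = trace - trace.mean()
    sd_p = c.std(axis=0)
    sd_b = b.std()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (c.T @ b) / (T * sd_p * sd_b)
    return r.reshape(data.shape[1:])


@dataclass
class GroupBrainBehavior:
    """Cross-mouse brain-behavior correlation summary."""

    mice: list[str]
    group_average: np.ndarray  # (F,) across-mouse averaged calcium trace
    single_trial_corr: dict[str, np.ndarray]  # per-mouse trial-to-average r
    correct_pair_corr: np.ndarray  # per-mouse averaged-trace vs own behavior
    shuffled_pair_corr: np.ndarray  # per-mouse mean over mismatched pairings
    all_shuffled: np.ndarray  # every mismatched pairing
    wilcoxon_p: float


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = np.std(a), np.std(b)
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def group_brain_behavior(
    calcium: Mapping[str, np.ndarray],
    behavior: Mapping[str, np.ndarray],
    min_trials: int = 20,
) -> GroupBrainBehavior:
    """Across-mouse calcium/behavior coupling with a shuffled-pair null.

    ``calcium[mouse]`` is (n_trials, F) single-trial region-averaged dF/F;
    ``behavior[mouse]`` is (n_trials, F) movement gradients on the same
    grid.  Mice with fewer than ``min_trials`` trials are excluded; at
    least 3 mice must remain.  Per-mouse trial averages are z-scored,
    averaged across mice, and each mouse's averaged calcium trace is
    correlated with its own (correct pair) and every other mouse's
    (mismatched pair) averaged behavior trace; the distributions are
    compared with a Wilcoxon signed-rank test.
    """
    mice = [m for m in calcium if calcium[m].shape[0] >= min_trials and m in behavior]
    if len(mice) < 3:
        raise ValueError("need at least 3 mice with enough trials")

    def zscore(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else x - x.mean()

    avg_cal = {m: zscore(np.asarray(calcium[m], float).mean(axis=0)) for m in mice}
    avg_beh = {m: zscore(np.asarray(behavior[m], float).mean(axis=0)) for m in mice}
    group_avg = np.mean([avg_cal[m] for m in mice], axis=0)

    single = {
        m: np.array([_pearson(zscore(tr), group_avg) for tr in np.asarray(calcium[m], float)])
        for m in mice
    }
    correct = np.array([_pearson(avg_cal[m], avg_beh[m]) for m in mice])
    shuffled_rows = []
    all_shuffled = []
    for m in mice:
        rs = [_pearson(avg_cal[m], avg_beh[o]) for o in mice if o != m]
        shuffled_rows.append(np.mean(rs))
        all_shuffled.extend(rs)
    shuffled = np.array(shuffled_rows)
    diff = correct - shuffled
    if np.allclose(diff, 0):
        p = 1.0
    else:
        p = float(_stats.wilcoxon(correct, shuffled).pvalue)
    return GroupBrainBehavior(
        mice=mice,
        group_average=group_avg,
        single_trial_corr=single,
        correct_pair_corr=correct,
        shuffled_pair_corr=shuffled,
        all_shuffled=np.asarray(all_shuffled),
        wilcoxon_p=p,
    )
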