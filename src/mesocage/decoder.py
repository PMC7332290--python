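"""Per-frame ridge-regression decoding of go-trial outcome.

A linear model y = b0 + X b with an L2 penalty lambda*||b||^2 predicts
trial outcome (+1 correct, -1 incorrect — early- or late-lick errors,
depending on pairing) from z-scored region-averaged dF/F0 at each frame of
the trial.  The penalty is selected by cross-validation on the training
folds; accuracy is the fraction of held-out trials whose sign(y_hat)
matches the label, averaged over repeated stratified k-fold runs.  Region
contributions are measured by reduced models: permuting one region's trial
assignment (-region) or every other region's (+region) and re-measuring
the maximum accuracy; a label-shuffled null calibrates chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .imaging import ATLAS, RoiSpec

__all__ = [
    "RoiTraceMatrix",
    "RidgeModel",
    "DecoderConfig",
    "DecoderResult",
    "extract_region_traces",
    "labels_from_outcomes",
    "fit_ridge",
    "cross_validated_accuracy",
    "reduced_models",
]

REGION_ORDER = ["ALM", "M2", "M1", "FL", "HL", "BC", "RS", "V1"]


@dataclass
class RoiTraceMatrix:
    """Trials x regions x frames of z-scored region-averaged dF/F0.

    Bilateral ROI pairs are averaged, so with the default 8-region
    parcellation R = 8.  ``frame_times`` are seconds relative to the cue.
    """

    X: np.ndarray  # (N, R, F)
    region_names: list[str]
    frame_times: np.ndarray  # (F,)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 3:
            raise ValueError("X must be (trials, regions, frames)")
        if self.X.shape[1] != len(self.region_names):
            raise ValueError("region_names must match the region axis")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("missing frames in trace matrix")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_frames(self) -> int:
        return self.X.shape[2]

    def frame(self, f: int) -> np.ndarray:
        return self.X[:, :, f]


@dataclass(frozen=True)
class RidgeModel:
    """Closed-form ridge fit at one frame: y_hat = b0 + X b."""

    beta0: float
    beta: np.ndarray  # (R,)
    lam: float
    frame: int = -1

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.beta0 + np.asarray(X, float) @ self.beta

    def classify(self, X: np.ndarray) -> np.ndarray:
        """sign(y_hat) with ties (exactly 0) assigned to the +1 class."""
        yhat = self.predict(X)
        return np.where(yhat >= 0, 1, -1)


@dataclass(frozen=True)
class DecoderConfig:
    """Cross-validation protocol; defaults are the full study conditions
    (50 runs of stratified 3-fold CV per frame, 1000 permutation
    iterations, 25 log-spaced penalties chosen on the training folds)."""

    folds: int = 3
    runs: int = 50
    lambdas: tuple[float, ...] = tuple(float(x) for x in np.logspace(-3, 3, 25))
    permutation_iterations: int = 1000
    pairing: str = "correct-vs-early"  # or "correct-vs-late"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")


@dataclass
class DecoderResult:
    """Per-frame decoding summary."""

    accuracy: np.ndarray  # (F,) mean over runs x folds
    coefficients: np.ndarray  # (F, R) mean training-fold coefficients
    chosen_lambda: np.ndarray  # (F,)
    majority_rate: float
    frame_times: np.ndarray
    region_names: list[str]
    importance: pd.DataFrame | None = None  # reduced-model table
    null_accuracy: np.ndarray | None = None  # label-shuffled max accuracies

    @property
    def max_accuracy(self) -> float:
        return float(np.max(self.accuracy))


def extract_region_traces(
    corrected: np.ndarray,
    rois: Mapping[str, RoiSpec] | None = None,
    mm_per_pixel: float = 8.2 / 64.0,
    bregma: tuple[int, int] = (24, 32),
    frame_times: np.ndarray | None = None,
    zscore: bool = True,
) -> RoiTraceMatrix:
    """Region-averaged traces from per-trial corrected dF/F movies.

    ``corrected`` is (trials, frames, H, W).  Each region is averaged over
    its 0.7 x 0.7 mm box, hemispheres averaged, then z-scored per region
    over all trials and frames.
    """
    arr = np.asarray(corrected, dtype=float)
    if arr.ndim != 4:
        raise ValueError("corrected must be (trials, frames, H, W)")
    rois = rois or {k: ATLAS[k] for k in REGION_ORDER}
    names = list(rois)
    N, F, H, W = arr.shape
    X = np.empty((N, len(names), F))
    for j, name in enumerate(names):
        boxes = rois[name].pixel_boxes((H, W), mm_per_pixel, bregma)
        hemis = [arr[:, :, r0:r1, c0:c1].mean(axis=(2, 3)) for r0, r1, c0, c1 in boxes]
        X[:, j, :] = np.mean(hemis, axis=0)
    if zscore:
        for j in range(len(names)):
            mu, sd = X[:, j, :].mean(), X[:, j, :].std()
            X[:, j, :] = (X[:, j, :] - mu) / sd if sd > 0 else X[:, j, :] - mu
    if frame_times is None:
        frame_times = np.arange(F, dtype=float)
    return RoiTraceMatrix(X=X, region_names=names, frame_times=np.asarray(frame_times, float))


def labels_from_outcomes(outcomes: Sequence[int], pairing: str = "correct-vs-early") -> np.ndarray:
    """Map outcome codes to +1/-1 labels for one correct-vs-error pairing.

    ``correct-vs-early`` keeps +2 vs -4; ``correct-vs-late`` keeps +2 vs
    -2; other codes map to 0 (caller should drop those trials).
    """
    err = {"correct-vs-early": -4, "correct-vs-late": -2}.get(pairing)
    if err is None:
        raise ValueError(f"unknown pairing {pairing!r}")
    arr = np.asarray(outcomes, dtype=int)
    out = np.zeros(len(arr), dtype=int)
    out[arr == 2] = 1
    out[arr == err] = -1
    return out


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float, frame: int = -1) -> RidgeModel:
    """Closed-form ridge solution with an unpenalized intercept.

    Minimizes ||y - b0 - X b||^2 + lam ||b||^2: center X and y, solve
    (Xc'Xc + lam I) b = Xc' yc, then b0 = mean(y) - mean(X) @ b.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be (N, R) matching y")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if np.all(y == y[0]):
        raise ValueError("labels are degenerate (single class)")
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    R = X.shape[1]
    beta = np.linalg.solve(Xc.T @ Xc + lam * np.eye(R), Xc.T @ yc)
    return RidgeModel(beta0=float(ym - xm @ beta), beta=beta, lam=float(lam), frame=frame)


def _ridge_path(Xc: np.ndarray, yc: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Coefficients for every lambda via one eigendecomposition of Xc'Xc."""
    G = Xc.T @ Xc
    w, V = np.linalg.eigh(G)
    b = V.T @ (Xc.T @ yc)
    return V @ (b[:, None] / (w[:, None] + lambdas[None, :]))  # (R, L)


def _select_lambda(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray, folds: int, rng: np.random.Generator
) -> float:
    """Inner-CV penalty selection by held-out sign accuracy."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(rng.integers(0, 2**31)))
    hits = np.zeros(len(lambdas))
    total = 0
    for tr, te in skf.split(X, y):
        Xtr, ytr = X[tr], y[tr].astype(float)
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        betas = _ridge_path(Xtr - xm, ytr - ym, lambdas)  # (R, L)
        yhat = (X[te] - xm) @ betas + ym  # (n_te, L)
        pred = np.where(yhat >= 0, 1, -1)
        hits += (pred == y[te][:, None]).sum(axis=0)
        total += len(te)
    # ties break toward the stronger penalty for stability
    best = np.flatnonzero(hits == hits.max())[-1]
    return float(lambdas[best])


def cross_validated_accuracy(
    matrix: RoiTraceMatrix,
    y: np.ndarray,
    config: DecoderConfig = DecoderConfig(),
    rng: np.random.Generator | None = None,
    frames: Sequence[int] | None = None,
) -> DecoderResult:
    """Repeated stratified k-fold decoding accuracy at every frame.

    For each frame: ``runs`` repetitions of stratified ``folds``-fold CV
    with per-run reshuffled fold assignment; the penalty is selected per
    frame on the training folds; test prediction is sign(y_hat); accuracy
    is averaged over runs and folds.
    """
    rng = rng or np.random.default_rng(0)
    y = np.asarray(y, dtype=int)
    if len(y) != matrix.n_trials:
        raise ValueError("labels must match trials")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes present")
    if counts.min() < config.folds:
        raise ValueError("a class has fewer members than folds")
    frame_list = list(frames) if frames is not None else list(range(matrix.n_frames))
    lambdas = np.asarray(config.lambdas)

    acc = np.zeros(len(frame_list))
    coefs = np.zeros((len(frame_list), matrix.X.shape[1]))
    lams = np.zeros(len(frame_list))
    for fi, f in enumerate(frame_list):
        Xf = matrix.frame(f)
        lam = _select_lambda(Xf, y, lambdas, config.folds, rng)
        lams[fi] = lam
        hits = 0
        total = 0
        coef_acc = np.zeros(matrix.X.shape[1])
        n_models = 0
        for _ in range(config.runs):
            skf = StratifiedKFold(
                n_splits=config.folds, shuffle=True, random_state=int(rng.integers(0, 2**31))
            )
            for tr, te in skf.split(Xf, y):
                model = fit_ridge(Xf[tr], y[tr], lam, frame=f)
                hits += int((model.classify(Xf[te]) == y[te]).sum())
                total += len(te)
                coef_acc += model.beta
                n_models += 1
        acc[fi] = hits / total
        coefs[fi] = coef_acc / n_models
    majority = counts.max() / counts.sum()
    return DecoderResult(
        accuracy=acc,
        coefficients=coefs,
        chosen_lambda=lams,
        majority_rate=float(majority),
        frame_times=matrix.frame_times[frame_list],
        region_names=list(matrix.region_names),
    )


def _max_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    config: DecoderConfig,
    rng: np.random.Generator,
    frames: Sequence[int],
) -> float:
    m = RoiTraceMatrix(X=X, region_names=[f"r{i}" for i in range(X.shape[1])], frame_times=np.arange(X.shape[2], dtype=float))
    res = cross_validated_accuracy(m, y, config, rng, frames=frames)
    return res.max_accuracy


def reduced_models(
    matrix: RoiTraceMatrix,
    y: np.ndarray,
    config: DecoderConfig = DecoderConfig(),
    rng: np.random.Generator | None = None,
    frames: Sequence[int] | None = None,
    full_result: DecoderResult | None = None,
) -> tuple[pd.DataFrame, np.ndarray, DecoderResult]:
    """Per-region permutation importance and a label-shuffled null.

    ``-region``: that region's trial assignment is permuted (consistently
    across frames) and the maximum accuracy re-measured; ``+region``:
    every *other* region is permuted.  Importance is the full-model
    maximum accuracy minus the mean reduced maximum.  The null permutes
    the labels themselves and records the resulting maxima.
    """
    rng = rng or np.random.default_rng(0)
    y = np.asarray(y, dtype=int)
    frame_list = list(frames) if frames is not None else list(range(matrix.n_frames))
    if full_result is None:
        full_result = cross_validated_accuracy(matrix, y, config, rng, frames=frame_list)
    full_max = full_result.max_accuracy

    rows = []
    for j, name in enumerate(matrix.region_names):
        minus_max = []
        plus_max = []
        for _ in range(config.permutation_iterations):
            perm = rng.permutation(matrix.n_trials)
            Xm = matrix.X.copy()
            Xm[:, j, :] = Xm[perm, j, :]
            minus_max.append(_max_accuracy(Xm, y, config, rng, frame_list))
            Xp = matrix.X.copy()
            for k in range(matrix.X.shape[1]):
                if k != j:
                    perm_k = rng.permutation(matrix.n_trials)
                    Xp[:, k, :] = Xp[perm_k, k, :]
            plus_max.append(_max_accuracy(Xp, y, config, rng, frame_list))
        rows.append(
            {
                "region": name,
                "minus_accuracy": float(np.mean(minus_max)),
                "plus_accuracy": float(np.mean(plus_max)),
                "minus_importance": full_max - float(np.mean(minus_max)),
                "plus_importance": float(np.mean(plus_max)) - full_result.majority_rate,
            }
        )
    importance = pd.DataFrame(rows)

    null = np.empty(config.permutation_iterations)
    for i in range(config.permutation_iterations):
        y_perm = rng.permutation(y)
        null[i] = _max_accuracy(matrix.X, y_perm, config, rng, frame_list)

    full_result.importance = importance
    full_result.null_accuracy = null
    return importance, null, full_result
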