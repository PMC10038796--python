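"""Model-mediated ISC: how much of the intersubject synchronization a
stimulus feature model accounts for.

A feature model (e.g. low-level acoustic energy, or high-level semantic
embeddings) is first orthogonalized against nuisance "editing" descriptors
(film cuts, scene transitions, dialogue/music presence), projected onto
the scan grid as a regression design, and regressed out of every subject's
data separately.  ISC recomputed on the residuals is the model-mediated
ISC; the *drop* (original minus mediated ISC) quantifies the model's role
as a mediator of synchronization.  Drops of two models are contrasted
voxelwise with a sign-flip Wilcoxon signed-rank permutation test using a
max-W familywise correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg, stats

from .isc import BoldGroup, isc_across
from . import permutation as perm

FEATURE_LEVELS = ("low_auditory", "low_visual", "high_semantic", "editing")


@dataclass
class FeatureModel:
    """A time-by-feature stimulus descriptor matrix at its native rate."""

    name: str
    level: str
    times_s: np.ndarray
    matrix: np.ndarray
    native_rate_hz: float

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[0] != self.times_s.size:
            raise ValueError(
                f"matrix has {self.matrix.shape[0]} rows for {self.times_s.size} times"
            )
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times_s must be strictly increasing")
        if self.level not in FEATURE_LEVELS:
            raise ValueError(f"level must be one of {FEATURE_LEVELS}")

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


@dataclass
class MediationResult:
    """Original vs model-mediated ISC and the per-voxel drop."""

    isc_original: np.ndarray
    isc_mediated: np.ndarray
    drop: np.ndarray
    n_pairs: int
    pair_drop: np.ndarray | None = None     # (n_pairs, n_voxels)
    p_drop: np.ndarray | None = None
    fwe_threshold: float | None = None
    significant_mask: np.ndarray | None = None


# ---------------------------------------------------------------------------
# orthogonalization
# ---------------------------------------------------------------------------

def _resample_to_times(model: FeatureModel, times_s: np.ndarray) -> np.ndarray:
    """Linear interpolation of a feature matrix onto a new time grid."""
    return np.column_stack([
        np.interp(times_s, model.times_s, model.matrix[:, j])
        for j in range(model.n_features)
    ])


def orthogonalize(model: FeatureModel, editing: FeatureModel) -> FeatureModel:
    """Residualize every model column against the editing descriptors.

    The editing matrix is resampled to the model's grid when needed; each
    model column is replaced by the residual of its least-squares regression
    on an intercept plus all (linearly independent) editing columns, so the
    output has zero correlation with every editing descriptor.
    Rank-deficient editing matrices are pruned with a warning.
    """
    E = editing.matrix if np.array_equal(editing.times_s, model.times_s) \
        else _resample_to_times(editing, model.times_s)
    n = model.times_s.size
    X = np.column_stack([np.ones(n), E])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # keep a maximal independent subset via pivoted QR
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        keep = np.sort(piv[:rank])
        warnings.warn(
            f"editing matrix rank-deficient: keeping {rank} of {X.shape[1]} columns",
            stacklevel=2,
        )
        X = X[:, keep]
    beta, *_ = np.linalg.lstsq(X, model.matrix, rcond=None)
    resid = model.matrix - X @ beta
    return FeatureModel(
        name=f"{model.name}_orth",
        level=model.level,
        times_s=model.times_s,
        matrix=resid,
        native_rate_hz=model.native_rate_hz,
    )


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def hrf_double_gamma(times_s: np.ndarray, peak_s: float = 5.0,
                     undershoot_s: float = 15.0, ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at ``times_s``.

    Gamma densities with unit scale peak at (shape - 1), so the positive
    lobe peaks at ``peak_s`` and the undershoot at ``undershoot_s``; the
    undershoot amplitude is 1/``ratio`` of the peak.  Normalized to unit
    peak height.
    """
    t = np.asarray(times_s, dtype=float)
    h = stats.gamma.pdf(t, peak_s + 1) - stats.gamma.pdf(t, undershoot_s + 1) / ratio
    peak = h.max()
    return h / peak if peak > 0 else h


def build_design(
    model: FeatureModel,
    tr_seconds: float,
    n_timepoints: int,
    run_lengths: Sequence[int],
    hrf: bool = True,
) -> np.ndarray:
    """Project a feature model onto the scan grid as a regression design.

    Each column is (optionally) convolved with the canonical double-gamma
    haemodynamic response at the model's native rate, averaged within each
    TR bin, and z-scored per run; one intercept column per run is appended.
    All-zero feature columns stay all-zero.
    """
    scan_dur = n_timepoints * tr_seconds
    model_dur = model.times_s[-1] + 1.0 / model.native_rate_hz
    if model_dur < scan_dur - 1e-9:
        raise ValueError(
            f"model covers {model_dur:.1f}s but the scan lasts {scan_dur:.1f}s"
        )
    M = model.matrix
    if hrf:
        dt = 1.0 / model.native_rate_hz
        kernel = hrf_double_gamma(np.arange(0, 32.0, dt))
        M = np.column_stack([
            np.convolve(M[:, j], kernel)[: M.shape[0]] for j in range(M.shape[1])
        ])
    # average within TR bins
    bins = np.floor(model.times_s / tr_seconds).astype(int)
    valid = bins < n_timepoints
    design = np.zeros((n_timepoints, M.shape[1]))
    counts = np.bincount(bins[valid], minlength=n_timepoints).astype(float)
    for j in range(M.shape[1]):
        sums = np.bincount(bins[valid], weights=M[valid, j], minlength=n_timepoints)
        with np.errstate(invalid="ignore"):
            design[:, j] = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    # z-score per run (degenerate columns left untouched)
    start = 0
    for length in run_lengths:
        seg = design[start:start + length]
        sd = seg.std(axis=0)
        mean = seg.mean(axis=0)
        nz = sd > 0
        seg[:, nz] = (seg[:, nz] - mean[nz]) / sd[nz]
        start += length
    # run intercepts
    intercepts = np.zeros((n_timepoints, len(run_lengths)))
    start = 0
    for i, length in enumerate(run_lengths):
        intercepts[start:start + length, i] = 1.0
        start += length
    return np.column_stack([design, intercepts])


# ---------------------------------------------------------------------------
# residualization and mediated ISC
# ---------------------------------------------------------------------------

def _residual_projector(design: np.ndarray, n_timepoints: int) -> np.ndarray:
    """Annihilator matrix P with P @ y = residuals of y on [design (+ intercept)]."""
    X = np.asarray(design, dtype=float)
    if X.shape[0] != n_timepoints:
        raise ValueError(
            f"design has {X.shape[0]} rows for {n_timepoints} timepoints"
        )
    ones = np.ones((n_timepoints, 1))
    # append a global intercept only if the constant is not already spanned
    pinv = np.linalg.pinv(X)
    if np.linalg.norm(ones[:, 0] - X @ (pinv @ ones[:, 0])) > 1e-8 * np.sqrt(n_timepoints):
        X = np.column_stack([X, ones])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    return np.eye(n_timepoints) - X @ np.linalg.pinv(X)


def residualize_bold(group: BoldGroup, design: np.ndarray) -> BoldGroup:
    """Regress the design out of every subject's every voxel series."""
    P = _residual_projector(design, group.n_timepoints)
    resid = group.data @ P.T
    return group.with_data(resid)


def mediated_isc(
    group_a: BoldGroup,
    group_b: BoldGroup,
    design_for_a: np.ndarray,
    design_for_b: np.ndarray,
) -> MediationResult:
    """Across-condition ISC before and after removing the model contribution.

    The designs may differ between groups: in the cross-modal setting,
    visual features are removed from the audio-only group and acoustic
    features from the visual-only group, while an inherently multimodal
    semantic model is removed from both.
    """
    raw = isc_across(group_a, group_b, keep_pairs=True)
    resid = isc_across(
        residualize_bold(group_a, design_for_a),
        residualize_bold(group_b, design_for_b),
        keep_pairs=True,
    )
    pair_drop = raw.pair_r - resid.pair_r
    return MediationResult(
        isc_original=raw.mean_r,
        isc_mediated=resid.mean_r,
        drop=raw.mean_r - resid.mean_r,
        n_pairs=raw.n_pairs,
        pair_drop=pair_drop,
    )


def drop_significance(
    result: MediationResult,
    group_a: BoldGroup,
    group_b: BoldGroup,
    design_for_a: np.ndarray,
    design_for_b: np.ndarray,
    spec: perm.SurrogateSpec,
    alpha: float = 0.05,
    grid=None,
    min_cluster: int = 20,
    connectivity: int = 18,
) -> MediationResult:
    """One-tailed permutation inference on the ISC drop.

    Per permutation, every subject's voxel series is replaced by a
    chunk-shuffle surrogate, the drop map is recomputed, and its maximum
    over voxels recorded.  p-values use the generalized-Pareto tail
    estimator; the FWE threshold is the 95th percentile (at alpha=0.05) of
    the max-drop distribution, optionally combined with a minimum cluster
    extent when a grid shape is supplied.
    """
    Pa = _residual_projector(design_for_a, group_a.n_timepoints)
    Pb = _residual_projector(design_for_b, group_b.n_timepoints)

    def drop_stat(ga: BoldGroup, gb: BoldGroup) -> np.ndarray:
        raw = isc_across(ga, gb, keep_pairs=False)
        res = isc_across(ga.with_data(ga.data @ Pa.T),
                         gb.with_data(gb.data @ Pb.T), keep_pairs=False)
        return raw.mean_r - res.mean_r

    null = perm.null_distribution(drop_stat, [group_a, group_b], spec)
    p_drop = perm.gpd_p_map(result.drop, null.per_voxel_stats)
    thr = perm.fwe_threshold(null, alpha)
    sig = perm.cluster_filter_flat(result.drop, thr, grid,
                                   min_size=min_cluster,
                                   connectivity=connectivity)
    return MediationResult(
        isc_original=result.isc_original,
        isc_mediated=result.isc_mediated,
        drop=result.drop,
        n_pairs=result.n_pairs,
        pair_drop=result.pair_drop,
        p_drop=p_drop,
        fwe_threshold=thr,
        significant_mask=sig,
    )


# ---------------------------------------------------------------------------
# low- vs high-level model contrast
# ---------------------------------------------------------------------------

@dataclass
class DropContrast:
    """Voxelwise signed-rank contrast of two models' per-pair ISC drops."""

    W: np.ndarray                      # per-voxel signed-rank statistic (NaN untestable)
    p: np.ndarray                      # two-sided per-voxel permutation p
    fwe_threshold_high: float          # max-W distribution quantile (first model larger)
    fwe_threshold_low: float           # min-W distribution quantile (second model larger)
    mask_first_greater: np.ndarray
    mask_second_greater: np.ndarray


def signed_rank_W(diff: np.ndarray) -> float:
    """Wilcoxon signed-rank W: sum of the ranks of positive differences.

    Zeros are dropped; ties get midranks.  Returns NaN when fewer than 5
    nonzero differences remain (untestable voxel).
    """
    d = np.asarray(diff, dtype=float)
    d = d[d != 0]
    if d.size < 5:
        return np.nan
    ranks = stats.rankdata(np.abs(d))
    return float(ranks[d > 0].sum())


def compare_model_drops(
    drop_pairs_low: np.ndarray,
    drop_pairs_high: np.ndarray,
    n_permutations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    exact: bool = False,
) -> DropContrast:
    """Contrast two models' drops with a sign-flip signed-rank permutation test.

    ``drop_pairs_*`` are (n_pairs, n_voxels) per-pair ISC drops.  Per voxel,
    W is the sum of ranks of positive (low - high) paired differences.  The
    null flips the sign of each pair's difference with probability 1/2 (the
    same flip pattern across voxels within a permutation, so the maximum
    and minimum of W over voxels give two-sided FWE thresholds).
    """
    low = np.asarray(drop_pairs_low, dtype=float)
    high = np.asarray(drop_pairs_high, dtype=float)
    if low.shape != high.shape:
        raise ValueError(f"shape mismatch: {low.shape} vs {high.shape}")
    d = low - high                                   # (P, V)
    n_pairs, n_vox = d.shape

    # per-voxel signed ranks of |d| over nonzero entries
    R = np.zeros_like(d)                             # rank if d>0 else 0
    ranks_abs = np.zeros_like(d)                     # rank of |d| (0 where d==0)
    testable = np.zeros(n_vox, dtype=bool)
    for v in range(n_vox):
        dv = d[:, v]
        nz = dv != 0
        if nz.sum() >= 5:
            testable[v] = True
            r = stats.rankdata(np.abs(dv[nz]))
            ranks_abs[nz, v] = r
            R[nz, v] = np.where(dv[nz] > 0, r, 0.0)
    W = np.where(testable, R.sum(axis=0), np.nan)

    if exact:
        if n_pairs > 20:
            raise ValueError("exact enumeration is limited to 20 pairs")
        codes = np.arange(2 ** n_pairs)
        keep = (codes[:, None] >> np.arange(n_pairs)[None, :]) & 1 == 1
        n_permutations = keep.shape[0]
    else:
        rng = np.random.default_rng(seed)
        keep = rng.random((n_permutations, n_pairs)) < 0.5  # True -> keep original sign
    # under sign flips, W' = sum of ranks whose flipped difference is positive:
    # rank counts when (keep and d>0) or (not keep and d<0)
    pos = (d > 0).astype(float)
    neg = (d < 0).astype(float)
    W_null = keep.astype(float) @ (ranks_abs * pos) + (~keep).astype(float) @ (ranks_abs * neg)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_hi = (1 + np.sum(W_null >= W[None, :], axis=0)) / (n_permutations + 1)
        p_lo = (1 + np.sum(W_null <= W[None, :], axis=0)) / (n_permutations + 1)
    p = np.where(testable, np.minimum(1.0, 2 * np.minimum(p_hi, p_lo)), np.nan)

    if testable.any():
        max_W = W_null[:, testable].max(axis=1)
        min_W = W_null[:, testable].min(axis=1)
        thr_hi = float(np.quantile(max_W, 1 - alpha))
        thr_lo = float(np.quantile(min_W, alpha))
    else:
        thr_hi, thr_lo = np.nan, np.nan
    with np.errstate(invalid="ignore"):
        mask_first = testable & (W >= thr_hi)
        mask_second = testable & (W <= thr_lo)
    return DropContrast(
        W=W,
        p=p,
        fwe_threshold_high=thr_hi,
        fwe_threshold_low=thr_lo,
        mask_first_greater=mask_first,
        mask_second_greater=mask_second,
    )
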