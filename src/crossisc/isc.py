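"""Intersubject correlation (ISC) maps and group comparisons.

ISC quantifies stimulus-locked processing as the Pearson correlation of
voxel time series between subjects watching (or listening to) the same
naturalistic stimulus.  Within-condition ISC averages the correlation over
all unordered subject pairs of one group; across-condition ISC pairs each
subject of one condition (e.g. audio-only) with each subject of the other
(e.g. visual-only), so that only modality-independent signal can drive it.

Per-voxel summary statistics follow the convention of dividing the mean
pair correlation by the standard error of the pair correlations, yielding
a t-like statistic whose null distribution is obtained nonparametrically
(see :mod:`crossisc.permutation`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats


class UndefinedCorrelationError(ValueError):
    """Raised when a Pearson correlation is requested for a zero-variance series."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class BoldGroup:
    """One experimental group's preprocessed BOLD data.

    Parameters
    ----------
    subject_ids
        One label per subject.
    data
        Array of shape ``(n_subjects, n_voxels, n_timepoints)`` in
        percent-signal-like units (zero mean per run is not assumed;
        per-run means are removed internally before correlating).
    tr_seconds
        Repetition time (sampling interval) in seconds.
    run_lengths
        Number of timepoints of each scanning run; must sum to the
        timepoint count.
    condition
        Stimulus condition label, e.g. ``"AV"``, ``"A"`` or ``"V"``.
    population
        Participant population label, e.g. ``"TD"``, ``"blind"``, ``"deaf"``.
    """

    subject_ids: Sequence[str]
    data: np.ndarray
    tr_seconds: float
    run_lengths: Sequence[int]
    condition: str = "AV"
    population: str = "TD"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (subjects, voxels, timepoints); got shape {self.data.shape}"
            )
        if len(self.subject_ids) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.subject_ids)} subject ids for {self.data.shape[0]} subjects"
            )
        self.run_lengths = tuple(int(r) for r in self.run_lengths)
        if sum(self.run_lengths) != self.data.shape[2]:
            raise ValueError(
                f"run_lengths {self.run_lengths} sum to {sum(self.run_lengths)}, "
                f"but data has {self.data.shape[2]} timepoints"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray) -> "BoldGroup":
        """Copy of this group with ``data`` replaced (metadata kept)."""
        return replace(self, data=data)


@dataclass
class IscMap:
    """Voxelwise ISC summary: mean pair r, t-statistic and (optionally) inference."""

    mean_r: np.ndarray
    n_pairs: int
    t_stat: np.ndarray
    pair_r: np.ndarray | None = None          # (n_pairs, n_voxels)
    p: np.ndarray | None = None
    fwe_threshold: float | None = None
    significant_mask: np.ndarray | None = None


@dataclass
class GroupComparison:
    """Region-level two-sample comparison of per-pair ISC values."""

    region: str
    W: float
    p_raw: float
    p_bonferroni: float
    n_pairs_a: int
    n_pairs_b: int
    mean_diff_r: float
    se_diff: float


# ---------------------------------------------------------------------------
# series preparation
# ---------------------------------------------------------------------------

def demean_by_run(data: np.ndarray, run_lengths: Sequence[int]) -> np.ndarray:
    """Remove the temporal mean of each run (last axis is time)."""
    data = np.asarray(data, dtype=float)
    out = np.empty_like(data)
    start = 0
    for length in run_lengths:
        seg = data[..., start:start + length]
        out[..., start:start + length] = seg - seg.mean(axis=-1, keepdims=True)
        start += length
    return out


def _normalize(data: np.ndarray) -> np.ndarray:
    """Mean-centre and scale each series (last axis) to unit L2 norm.

    Zero-variance series become all-NaN so downstream statistics can flag
    the voxel as invalid rather than silently producing 0/0.
    """
    centred = data - data.mean(axis=-1, keepdims=True)
    norm = np.linalg.norm(centred, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = centred / norm
    out[np.broadcast_to(norm == 0, out.shape)] = np.nan
    return out


def pairwise_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between two equal-length series.

    Raises
    ------
    UndefinedCorrelationError
        If either series has zero variance.
    ValueError
        On length mismatch, fewer than 3 points, or non-finite values.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"series shapes differ: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need at least 3 timepoints")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("series contain non-finite values")
    for name, s in (("x", x), ("y", y)):
        if np.ptp(s) == 0:
            raise UndefinedCorrelationError(f"series {name!r} has zero variance")
    return float(stats.pearsonr(x, y)[0])


# ---------------------------------------------------------------------------
# ISC maps
# ---------------------------------------------------------------------------

def _prepare(group: BoldGroup) -> np.ndarray:
    """Run-demeaned, unit-norm subject series ready for dot-product correlation."""
    return _normalize(demean_by_run(group.data, group.run_lengths))


def _summarize_pairs(pair_r: np.ndarray, keep_pairs: bool) -> IscMap:
    n_pairs = pair_r.shape[0]
    invalid = np.isnan(pair_r).any(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_r = pair_r.mean(axis=0)
        if n_pairs > 1:
            se = pair_r.std(axis=0, ddof=1) / np.sqrt(n_pairs)
            with np.errstate(invalid="ignore", divide="ignore"):
                t_stat = mean_r / se
        else:
            t_stat = np.full_like(mean_r, np.nan)
    mean_r = np.where(invalid, np.nan, mean_r)
    t_stat = np.where(invalid, np.nan, t_stat)
    return IscMap(
        mean_r=mean_r,
        n_pairs=n_pairs,
        t_stat=t_stat,
        pair_r=pair_r if keep_pairs else None,
    )


def isc_within(group: BoldGroup, keep_pairs: bool = True) -> IscMap:
    """Within-condition ISC: mean Pearson r over all N(N-1)/2 subject pairs."""
    if group.n_subjects < 3:
        raise ValueError("within-condition ISC needs at least 3 subjects")
    z = _prepare(group)
    corr = np.einsum("avt,bvt->abv", z, z)          # (S, S, V)
    iu = np.triu_indices(group.n_subjects, k=1)
    pair_r = corr[iu]                               # (n_pairs, V)
    return _summarize_pairs(pair_r, keep_pairs)


def isc_across(group_a: BoldGroup, group_b: BoldGroup, keep_pairs: bool = True) -> IscMap:
    """Across-condition ISC: mean r over all N_A x N_B cross-condition pairs.

    Only pairs that straddle the two conditions are used, so within-group
    correlations never contribute.
    """
    if group_a.data.shape[1:] != group_b.data.shape[1:]:
        raise ValueError(
            f"group shapes differ: {group_a.data.shape} vs {group_b.data.shape}"
        )
    if group_a.tr_seconds != group_b.tr_seconds:
        raise ValueError(
            f"TR differs: {group_a.tr_seconds} vs {group_b.tr_seconds}"
        )
    za = _prepare(group_a)
    zb = _prepare(group_b)
    corr = np.einsum("avt,bvt->abv", za, zb)        # (S_A, S_B, V)
    pair_r = corr.reshape(-1, corr.shape[2])
    return _summarize_pairs(pair_r, keep_pairs)


def isc_map_stat(group_a: BoldGroup, group_b: BoldGroup | None = None,
                 statistic: str = "t") -> np.ndarray:
    """Per-voxel ISC statistic vector, for use as a permutation ``stat_fn``.

    ``statistic`` is ``"t"`` (mean r over its standard error) or ``"mean_r"``.
    """
    m = isc_within(group_a, keep_pairs=False) if group_b is None \
        else isc_across(group_a, group_b, keep_pairs=False)
    return m.t_stat if statistic == "t" else m.mean_r


def conjunction(maps: Sequence[IscMap]) -> np.ndarray:
    """Voxelwise logical AND of the significance masks of several maps."""
    if not maps:
        raise ValueError("need at least one map")
    masks = []
    for m in maps:
        if m.significant_mask is None:
            raise ValueError("every map needs significant_mask set")
        masks.append(np.asarray(m.significant_mask, dtype=bool))
    shape = masks[0].shape
    for m in masks[1:]:
        if m.shape != shape:
            raise ValueError(f"mask grids differ: {shape} vs {m.shape}")
    out = masks[0].copy()
    for m in masks[1:]:
        out &= m
    return out


# ---------------------------------------------------------------------------
# ROI pair matrix and group comparison
# ---------------------------------------------------------------------------

def roi_pair_matrix(
    groups: Sequence[BoldGroup],
    roi_mask: np.ndarray,
    pair_threshold_p: float = 0.05,
    surrogate_spec=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Subject-by-subject ISC matrix of an ROI-mean time series.

    The ROI series of each subject is the spatial mean over ``roi_mask``
    voxels.  All subjects of all supplied groups enter one symmetric
    correlation matrix with a unit diagonal.  Each off-diagonal pair is
    tested one-tailed against a chunk-shuffle surrogate null (see
    :func:`crossisc.permutation.surrogate_series`); entries with
    p >= ``pair_threshold_p`` are flagged False in the returned mask.

    Returns ``(r_matrix, significant_mask)``.
    """
    from . import permutation as perm

    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.sum() == 0:
        raise ValueError("ROI mask is empty")
    if not groups:
        raise ValueError("need at least one group")
    run_lengths = groups[0].run_lengths
    series = []
    for g in groups:
        if g.run_lengths != run_lengths:
            raise ValueError("groups must share run structure")
        series.append(g.data[:, roi_mask, :].mean(axis=1))
    series = np.concatenate(series, axis=0)          # (n_total, T)
    z = _normalize(demean_by_run(series, run_lengths))
    r = z @ z.T
    np.fill_diagonal(r, 1.0)

    spec = surrogate_spec if surrogate_spec is not None else perm.SurrogateSpec()
    rng = np.random.default_rng(spec.seed)
    n = series.shape[0]
    # surrogate null of the pair correlation: both series surrogated
    idx_a = perm.surrogate_indices(run_lengths, spec, rng, spec.n_permutations)
    idx_b = perm.surrogate_indices(run_lengths, spec, rng, spec.n_permutations)
    sig = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            null_r = np.einsum(
                "pt,pt->p",
                _normalize(z[i][idx_a]),
                _normalize(z[j][idx_b]),
            )
            p = (1 + np.sum(null_r >= r[i, j])) / (spec.n_permutations + 1)
            sig[i, j] = sig[j, i] = p < pair_threshold_p
    return r, sig


def compare_groups(
    pair_r_a: np.ndarray,
    pair_r_b: np.ndarray,
    n_regions: int,
    region: str = "",
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two samples of pair ISC values.

    ``W`` is the sum of the (mid)ranks of sample A in the pooled ranking;
    the p-value is Bonferroni-corrected for ``n_regions`` regions.
    """
    a = np.asarray(pair_r_a, dtype=float)
    b = np.asarray(pair_r_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    W = float(ranks[: a.size].sum())
    p_raw = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    se = np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size) \
        if (a.size > 1 and b.size > 1) else np.nan
    return GroupComparison(
        region=region,
        W=W,
        p_raw=p_raw,
        p_bonferroni=min(1.0, p_raw * n_regions),
        n_pairs_a=int(a.size),
        n_pairs_b=int(b.size),
        mean_diff_r=float(a.mean() - b.mean()),
        se_diff=float(se),
    )


def spherical_roi_mask(
    mask_shape: tuple[int, int, int],
    centre_ijk: tuple[int, int, int],
    radius_mm: float = 6.0,
    voxel_size_mm: float = 3.0,
) -> np.ndarray:
    """Boolean sphere of ``radius_mm`` around a voxel-grid centre."""
    grid = np.indices(mask_shape).astype(float)
    d2 = sum((grid[k] - centre_ijk[k]) ** 2 for k in range(3)) * voxel_size_mm ** 2
    return d2 <= radius_mm ** 2
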