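"""Nonparametric inference machinery shared by every analysis stage.

The null model destroys stimulus locking while preserving the amplitude
distribution and most of the autocorrelation of each series: every run is
spliced into a fixed number of contiguous chunks, all chunks (pooled over
runs) are globally re-arranged, and each chunk is independently
time-reversed with probability 1/2.  Statistic maps recomputed on such
surrogate data build the permutation null; tail p-values are refined with
a generalized Pareto fit so that p-values far below 1/n_permutations are
estimable; familywise error is controlled with the distribution of the
maximum statistic over voxels, optionally combined with a minimum
cluster extent on the 3-D grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from skimage import measure


@dataclass
class SurrogateSpec:
    """Parameters of the chunk-shuffle surrogate null.

    ``chunks_per_run=3`` with six runs reproduces the 18-chunk splicing
    scheme; ``allow_time_reversal`` toggles the random per-chunk reversal.
    """

    chunks_per_run: int = 3
    allow_time_reversal: bool = True
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chunks_per_run < 1:
            raise ValueError("chunks_per_run must be >= 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class NullDistribution:
    """Permutation null: per-voxel statistics and their per-permutation maximum."""

    per_voxel_stats: np.ndarray      # (n_permutations, n_voxels)
    max_stat: np.ndarray             # (n_permutations,)
    seed: int

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez_compressed(path, per_voxel_stats=self.per_voxel_stats,
                            max_stat=self.max_stat)
        path.with_suffix(".json").write_text(
            json.dumps({"seed": self.seed,
                        "n_permutations": int(self.per_voxel_stats.shape[0]),
                        "n_voxels": int(self.per_voxel_stats.shape[1])}))

    @classmethod
    def load(cls, path: str | Path) -> "NullDistribution":
        path = Path(path)
        arrays = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(per_voxel_stats=arrays["per_voxel_stats"],
                   max_stat=arrays["max_stat"], seed=meta["seed"])


# ---------------------------------------------------------------------------
# surrogate construction
# ---------------------------------------------------------------------------

def chunk_slices(run_lengths: Sequence[int], chunks_per_run: int) -> list[tuple[int, int]]:
    """Contiguous (start, stop) chunk boundaries, pooling runs in order.

    Each run is split into ``chunks_per_run`` chunks of equal floor length;
    remainder timepoints go to the run's last chunk.
    """
    slices: list[tuple[int, int]] = []
    offset = 0
    for length in run_lengths:
        if length < chunks_per_run:
            raise ValueError(
                f"run of {length} timepoints is shorter than {chunks_per_run} chunks"
            )
        base = length // chunks_per_run
        for c in range(chunks_per_run):
            start = offset + c * base
            stop = offset + (c + 1) * base if c < chunks_per_run - 1 else offset + length
            slices.append((start, stop))
        offset += length
    return slices


def surrogate_indices(
    run_lengths: Sequence[int],
    spec: SurrogateSpec,
    rng: np.random.Generator,
    n_series: int,
) -> np.ndarray:
    """Time-index arrays implementing ``n_series`` independent surrogates.

    Returns an integer array of shape ``(n_series, T)``; gathering a series
    with one row yields one surrogate.  Chunk order is permuted globally
    across runs and each chunk is independently reversed with probability
    1/2 (if enabled), so the value multiset is always preserved exactly.
    """
    slices = chunk_slices(run_lengths, spec.chunks_per_run)
    n_chunks = len(slices)
    total = sum(run_lengths)
    lengths = np.array([stop - start for start, stop in slices])
    perms = np.argsort(rng.random((n_series, n_chunks)), axis=1)
    if spec.allow_time_reversal:
        reverse = rng.random((n_series, n_chunks)) < 0.5
    else:
        reverse = np.zeros((n_series, n_chunks), dtype=bool)

    if np.all(lengths == lengths[0]):
        # uniform chunk length: fully vectorized gather
        L = int(lengths[0])
        base = np.array([np.arange(start, stop) for start, stop in slices])  # (C, L)
        idx = base[perms]                                  # (n_series, C, L)
        rev_sel = np.take_along_axis(reverse, perms, axis=1)
        idx = np.where(rev_sel[..., None], idx[..., ::-1], idx)
        return idx.reshape(n_series, total)

    out = np.empty((n_series, total), dtype=np.intp)
    chunk_idx = [np.arange(start, stop) for start, stop in slices]
    for s in range(n_series):
        parts = []
        for c in perms[s]:
            part = chunk_idx[c]
            parts.append(part[::-1] if reverse[s, c] else part)
        out[s] = np.concatenate(parts)
    return out


def surrogate_series(
    ts: np.ndarray,
    run_lengths: Sequence[int],
    spec: SurrogateSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """One chunk-shuffle surrogate of a single time series."""
    ts = np.asarray(ts)
    if ts.ndim != 1 or ts.size != sum(run_lengths):
        raise ValueError(
            f"series length {ts.size} does not match run_lengths sum {sum(run_lengths)}"
        )
    idx = surrogate_indices(run_lengths, spec, rng, 1)[0]
    return ts[idx]


def surrogate_group_data(
    data: np.ndarray,
    run_lengths: Sequence[int],
    spec: SurrogateSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Independent surrogate for every (subject, voxel) series of a group array."""
    S, V, T = data.shape
    idx = surrogate_indices(run_lengths, spec, rng, S * V)
    flat = data.reshape(S * V, T)
    return np.take_along_axis(flat, idx, axis=1).reshape(S, V, T)


def null_distribution(
    stat_fn: Callable[..., np.ndarray],
    groups: Sequence,
    spec: SurrogateSpec,
) -> NullDistribution:
    """Permutation null of a per-voxel statistic map.

    For each of ``spec.n_permutations`` permutations, every subject's every
    voxel series in every group is replaced by an independent surrogate and
    ``stat_fn(*groups)`` is re-evaluated; the per-voxel statistics and their
    maximum over voxels are recorded.  Reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    maxima = []
    for k in range(spec.n_permutations):
        surr_groups = []
        for g in groups:
            surr = surrogate_group_data(g.data, g.run_lengths, spec, rng)
            surr_groups.append(g.with_data(surr))
        try:
            row = np.asarray(stat_fn(*surr_groups), dtype=float)
        except Exception as exc:                       # noqa: BLE001
            raise RuntimeError(f"stat_fn failed at permutation {k}") from exc
        rows.append(row)
        maxima.append(np.nanmax(row) if np.isfinite(row).any() else np.nan)
    per_voxel = np.vstack(rows)
    return NullDistribution(per_voxel_stats=per_voxel,
                            max_stat=np.asarray(maxima), seed=spec.seed)


# ---------------------------------------------------------------------------
# tail p-values
# ---------------------------------------------------------------------------

def _anderson_darling_gpd(exceedances: np.ndarray, c: float, scale: float) -> bool:
    """True if the GPD fit is acceptable at roughly the 5% level.

    Uses the A2 statistic with shape-dependent critical values interpolated
    from published tables for the GPD with both parameters estimated.
    """
    z = stats.genpareto.cdf(np.sort(exceedances), c, loc=0, scale=scale)
    z = np.clip(z, 1e-12, 1 - 1e-12)
    n = z.size
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(z) + np.log(1 - z[::-1])))
    # critical values rise with the (scipy-convention) shape c
    grid_c = np.array([-0.9, -0.5, -0.2, 0.0, 0.2, 0.5])
    grid_crit = np.array([0.77, 0.87, 0.98, 1.06, 1.14, 1.28])
    crit = float(np.interp(c, grid_c, grid_crit))
    return a2 <= crit


def gpd_p(observed: float, null_samples: np.ndarray) -> float:
    """Permutation p-value with a generalized-Pareto tail refinement.

    The base estimate is the never-zero counting estimator
    ``(1 + #{null >= observed}) / (n + 1)``.  When the observed statistic is
    in the extreme tail (empirical p < 0.10), a GPD is fitted by maximum
    likelihood to the exceedances above the 90th percentile and the tail
    probability is read off the fitted survival function; the fit threshold
    is raised (10 exceedances dropped at a time) while an Anderson-Darling
    check rejects, falling back to the counting estimate when fewer than 30
    exceedances remain.
    """
    if not np.isfinite(observed):
        raise ValueError("observed statistic must be finite")
    null = np.asarray(null_samples, dtype=float)
    null = null[np.isfinite(null)]
    n = null.size
    if n < 1:
        raise ValueError("need at least one null sample")
    p_emp = (1 + np.sum(null >= observed)) / (n + 1)
    # tail refinement needs a reasonably sampled null; below 50 samples the
    # counting estimator is all the data supports
    if n < 50 or p_emp >= 0.10:
        return float(p_emp)

    srt = np.sort(null)[::-1]                       # descending
    m = int(np.floor(0.10 * n))
    while m >= 30:
        # threshold halfway between the m-th and (m+1)-th largest values
        u = 0.5 * (srt[m - 1] + srt[m]) if m < n else srt[-1]
        exceed = srt[:m] - u
        if observed <= u:
            break
        try:
            c, _, scale = stats.genpareto.fit(exceed, floc=0)
        except Exception:                            # noqa: BLE001
            break
        if _anderson_darling_gpd(exceed, c, scale):
            tail = stats.genpareto.sf(observed - u, c, loc=0, scale=scale)
            p = (m / n) * tail
            return float(max(p, np.finfo(float).tiny))
        m -= 10
    return float(p_emp)


def gpd_p_map(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
    """One-tailed :func:`gpd_p` per voxel; NaN observed values give NaN p."""
    observed = np.asarray(observed, dtype=float)
    out = np.full(observed.shape, np.nan)
    for v in range(observed.size):
        if np.isfinite(observed[v]):
            out[v] = gpd_p(observed[v], null[:, v])
    return out


# ---------------------------------------------------------------------------
# familywise error control
# ---------------------------------------------------------------------------

def fwe_threshold(null: NullDistribution, alpha: float = 0.05) -> float:
    """(1 - alpha) quantile of the maximum-statistic distribution."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    max_stat = null.max_stat[np.isfinite(null.max_stat)]
    return float(np.quantile(max_stat, 1 - alpha))


def cluster_filter(
    stat: np.ndarray,
    threshold: float,
    min_size: int = 20,
    connectivity: int = 18,
) -> np.ndarray:
    """Supra-threshold mask on a 3-D grid after minimum-cluster-extent filtering.

    ``connectivity`` is the neighbourhood definition in voxels: 6 (faces),
    18 (faces+edges) or 26 (faces+edges+corners).
    """
    conn_map = {6: 1, 18: 2, 26: 3}
    if connectivity not in conn_map:
        raise ValueError(f"connectivity must be one of {sorted(conn_map)}")
    stat = np.asarray(stat, dtype=float)
    if stat.ndim != 3:
        raise ValueError("stat must be a 3-D volume")
    supra = np.nan_to_num(stat, nan=-np.inf) >= threshold
    labels = measure.label(supra, connectivity=conn_map[connectivity])
    out = np.zeros_like(supra)
    for region in measure.regionprops(labels):
        if region.area >= min_size:
            out[labels == region.label] = True
    return out


def cluster_filter_flat(
    stat_flat: np.ndarray,
    threshold: float,
    grid,
    min_size: int = 20,
    connectivity: int = 18,
) -> np.ndarray:
    """Cluster-extent filtering of a flat voxel vector.

    ``grid`` is either a 3-D grid shape (the vector fills the whole grid)
    or a 3-D boolean mask whose True voxels, in ascending linear order,
    correspond to the vector entries; ``None`` skips cluster filtering and
    applies the plain threshold.  Returns a flat boolean mask.
    """
    stat_flat = np.asarray(stat_flat, dtype=float)
    if grid is None:
        return np.nan_to_num(stat_flat, nan=-np.inf) >= threshold
    mask = np.ones(grid, dtype=bool) if isinstance(grid, tuple) \
        else np.asarray(grid, dtype=bool)
    if int(mask.sum()) != stat_flat.size:
        raise ValueError(
            f"{stat_flat.size} stat values for {int(mask.sum())} grid voxels"
        )
    vol = np.full(mask.shape, -np.inf)
    vol[mask] = np.nan_to_num(stat_flat, nan=-np.inf)
    return cluster_filter(vol, threshold, min_size, connectivity)[mask]
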