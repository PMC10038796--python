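"""Tests of the surrogate null, GPD tail p-values, FWE and cluster filtering."""

from itertools import permutations, product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossisc import (
    SurrogateSpec, surrogate_series, null_distribution, gpd_p,
    fwe_threshold, cluster_filter,
)
from crossisc.permutation import (
    NullDistribution, chunk_slices, surrogate_group_data, gpd_p_map,
    cluster_filter_flat,
)
from conftest import make_group


def enumerate_surrogates(ts, run_lengths, chunks_per_run, allow_reversal=True):
    """All surrogate series reachable by chunk shuffling + reversal."""
    slices = chunk_slices(run_lengths, chunks_per_run)
    chunks = [list(ts[a:b]) for a, b in slices]
    out = set()
    rev_opts = [(False, True)] * len(chunks) if allow_reversal \
        else [(False,)] * len(chunks)
    for order in permutations(range(len(chunks))):
        for rev in product(*rev_opts):
            parts = []
            for c in order:
                parts.extend(chunks[c][::-1] if rev[c] else chunks[c])
            out.add(tuple(parts))
    return out


class TestSurrogates:
    def test_constant_series_unchanged(self):
        ts = np.full(12, 3.5)
        out = surrogate_series(ts, (6, 6), SurrogateSpec(seed=0),
                               np.random.default_rng(0))
        np.testing.assert_array_equal(out, ts)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 3), st.integers(6, 20))
    def test_multiset_and_moments_preserved(self, seed, chunks, run_len):
        rng = np.random.default_rng(seed)
        ts = rng.standard_normal(2 * run_len)
        out = surrogate_series(ts, (run_len, run_len),
                               SurrogateSpec(chunks_per_run=chunks, seed=seed), rng)
        np.testing.assert_array_equal(np.sort(out), np.sort(ts))
        assert out.mean() == pytest.approx(ts.mean())
        assert out.std() == pytest.approx(ts.std())

    def test_drawn_surrogates_are_members_of_enumerated_set(self):
        ts = np.arange(6.0)
        universe = enumerate_surrogates(ts, (6,), 3)
        # 3 chunks of 2 samples: 3! orders x 2^3 reversals, some coinciding
        assert len(universe) <= 48
        rng = np.random.default_rng(5)
        spec = SurrogateSpec(chunks_per_run=3, seed=5)
        drawn = {tuple(surrogate_series(ts, (6,), spec, rng)) for _ in range(200)}
        assert drawn <= universe
        assert len(drawn) > 1

    def test_short_run_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            surrogate_series(np.arange(4.0), (2, 2),
                             SurrogateSpec(chunks_per_run=3),
                             np.random.default_rng(0))

    def test_remainder_goes_to_last_chunk(self):
        assert chunk_slices((7,), 3) == [(0, 2), (2, 4), (4, 7)]

    def test_group_surrogates_independent_per_voxel(self):
        g = make_group(n_subjects=2, n_voxels=4, n_timepoints=24,
                       run_lengths=(12, 12), seed=0)
        out = surrogate_group_data(g.data, g.run_lengths,
                                   SurrogateSpec(seed=0), np.random.default_rng(0))
        assert out.shape == g.data.shape
        for s in range(2):
            for v in range(4):
                np.testing.assert_array_equal(np.sort(out[s, v]),
                                              np.sort(g.data[s, v]))
        assert not np.array_equal(out[0, 0], out[0, 1])


class TestNullDistribution:
    def test_single_permutation_and_constant_stat(self):
        g = make_group(seed=3)
        null = null_distribution(lambda grp: np.full(grp.n_voxels, 2.5),
                                 [g], SurrogateSpec(n_permutations=1, seed=0))
        assert null.per_voxel_stats.shape == (1, g.n_voxels)
        assert np.all(null.per_voxel_stats == 2.5)
        assert null.max_stat[0] == 2.5

    def test_reproducible_from_seed(self):
        g = make_group(seed=4)
        stat = lambda grp: grp.data.mean(axis=(0, 2))
        spec = SurrogateSpec(n_permutations=5, seed=42)
        a = null_distribution(stat, [g], spec)
        b = null_distribution(stat, [g], spec)
        np.testing.assert_array_equal(a.per_voxel_stats, b.per_voxel_stats)

    def test_save_load_roundtrip(self, tmp_path):
        null = NullDistribution(np.arange(12.0).reshape(3, 4),
                                np.array([3.0, 7.0, 11.0]), seed=9)
        null.save(tmp_path / "null.npz")
        back = NullDistribution.load(tmp_path / "null.npz")
        np.testing.assert_array_equal(back.per_voxel_stats, null.per_voxel_stats)
        assert back.seed == 9


class TestGpdP:
    def test_counting_estimator(self):
        null = np.arange(999.0)
        # observed below the median: empirical branch
        assert gpd_p(100.0, null) > 0.5
        # observed equal to the maximum: (1 + 1) / (999 + 1)
        rng_null = np.random.default_rng(0).standard_normal(999)
        obs = rng_null.max()
        k = np.sum(rng_null >= obs)
        assert (1 + k) / 1000 == pytest.approx(0.002)

    def test_exponential_tail(self):
        # P(X >= 9.21) for a standard exponential is e^-9.21 ~ 1e-4
        null = np.random.default_rng(0).standard_exponential(10_000)
        p = gpd_p(9.21, null)
        assert np.exp(-9.21) / 1.5 <= p <= np.exp(-9.21) * 1.5

    def test_agrees_with_empirical_in_bulk(self):
        null = np.random.default_rng(1).standard_normal(10_000)
        for target in (0.01, 0.05, 0.2, 0.5):
            obs = np.quantile(null, 1 - target)
            p_emp = (1 + np.sum(null >= obs)) / (len(null) + 1)
            p = gpd_p(float(obs), null)
            assert abs(p - p_emp) / p_emp <= 0.20

    def test_small_null_falls_back_to_counting(self):
        null = np.arange(10.0)
        assert gpd_p(9.0, null) == pytest.approx(2 / 11)

    def test_nonfinite_observed_rejected(self):
        with pytest.raises(ValueError):
            gpd_p(np.nan, np.arange(100.0))

    def test_map_propagates_nan(self):
        null = np.random.default_rng(2).standard_normal((200, 3))
        obs = np.array([0.0, np.nan, 1.0])
        p = gpd_p_map(obs, null)
        assert np.isnan(p[1]) and np.isfinite(p[[0, 2]]).all()


class TestFweThreshold:
    def test_quantile_of_max_stat(self):
        null = NullDistribution(np.zeros((100, 1)),
                                np.arange(1.0, 101.0), seed=0)
        assert fwe_threshold(null, 0.05) == pytest.approx(
            np.quantile(np.arange(1.0, 101.0), 0.95))

    def test_boundary_alpha_near_one(self):
        null = NullDistribution(np.zeros((100, 1)),
                                np.arange(1.0, 101.0), seed=0)
        assert fwe_threshold(null, 1 - 1 / 100) <= 2.0

    def test_monotone_in_alpha(self):
        null = NullDistribution(np.zeros((50, 1)),
                                np.random.default_rng(3).standard_normal(50), 0)
        alphas = [0.01, 0.05, 0.1, 0.5, 0.9]
        thr = [fwe_threshold(null, a) for a in alphas]
        assert all(t1 >= t2 for t1, t2 in zip(thr, thr[1:]))


def flood_fill_labels(mask, connectivity):
    """Independent BFS flood-fill for the cluster oracle."""
    offsets = []
    for d in product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        order = sum(abs(x) for x in d)
        if (connectivity == 6 and order == 1) or \
           (connectivity == 18 and order <= 2) or connectivity == 26:
            offsets.append(d)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for idx in zip(*np.nonzero(mask)):
        if labels[idx]:
            continue
        current += 1
        stack = [idx]
        labels[idx] = current
        while stack:
            x, y, z = stack.pop()
            for dx, dy, dz in offsets:
                n = (x + dx, y + dy, z + dz)
                if all(0 <= n[k] < mask.shape[k] for k in range(3)) \
                        and mask[n] and not labels[n]:
                    labels[n] = current
                    stack.append(n)
    return labels


class TestClusterFilter:
    def test_all_subthreshold_empty(self):
        assert not cluster_filter(np.zeros((4, 4, 4)), 1.0, min_size=1).any()

    def test_twenty_voxel_line_boundary(self):
        vol = np.zeros((25, 3, 3))
        vol[:20, 1, 1] = 5.0
        assert cluster_filter(vol, 1.0, min_size=20).sum() == 20
        vol[19, 1, 1] = 0.0
        assert not cluster_filter(vol, 1.0, min_size=20).any()

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(7)
        stat = rng.standard_normal((8, 8, 8))
        got = cluster_filter(stat, 0.8, min_size=3, connectivity=connectivity)
        labels = flood_fill_labels(stat >= 0.8, connectivity)
        expected = np.zeros_like(got)
        for lab in range(1, labels.max() + 1):
            comp = labels == lab
            if comp.sum() >= 3:
                expected |= comp
        np.testing.assert_array_equal(got, expected)

    def test_unknown_connectivity_rejected(self):
        with pytest.raises(ValueError):
            cluster_filter(np.zeros((3, 3, 3)), 0.0, connectivity=10)

    def test_flat_filtering_through_partial_mask(self):
        mask = np.zeros((3, 3, 3), bool)
        mask.ravel()[:20] = True
        stat = np.zeros(20)
        stat[:10] = 5.0
        out = cluster_filter_flat(stat, 1.0, mask, min_size=5, connectivity=26)
        assert out.shape == (20,)
        assert out[:10].all() and not out[10:].any()
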