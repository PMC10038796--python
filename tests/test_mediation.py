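"""Tests of orthogonalization, design building, residualization and the
model-mediated ISC drop machinery."""

import numpy as np
import pytest

from crossisc import (
    FeatureModel, SimSpec, generate_bold_groups, generate_feature_models,
    orthogonalize, build_design, residualize_bold, mediated_isc,
    compare_model_drops,
)
from crossisc.mediation import hrf_double_gamma, signed_rank_W
from crossisc.simulate import _resampled_design
from conftest import make_group


def feature(matrix, times=None, level="high_semantic", rate=0.5):
    matrix = np.atleast_2d(np.asarray(matrix, float))
    if matrix.shape[0] == 1:
        matrix = matrix.T
    if times is None:
        times = np.arange(matrix.shape[0]) / rate
    return FeatureModel("m", level, times, matrix, rate)


class TestOrthogonalize:
    def test_spanned_column_becomes_zero(self):
        rng = np.random.default_rng(0)
        E = rng.standard_normal((50, 2))
        model = feature(E @ np.array([1.5, -2.0]))
        editing = feature(E, level="editing")
        out = orthogonalize(model, editing)
        assert np.abs(out.matrix).max() < 1e-10

    def test_orthogonal_column_only_demeaned(self):
        rng = np.random.default_rng(1)
        E = rng.standard_normal((200, 2))
        u = rng.standard_normal(200)
        X = np.column_stack([np.ones(200), E])
        u -= X @ np.linalg.lstsq(X, u, rcond=None)[0]   # make exactly orthogonal
        out = orthogonalize(feature(u + 3.0), feature(E, level="editing"))
        np.testing.assert_allclose(out.matrix[:, 0], u, atol=1e-10)

    def test_residuals_uncorrelated_with_editing(self):
        spec = SimSpec(n_subjects_per_group=3, n_voxels=4, n_timepoints=300,
                       run_lengths=(150, 150), voxel_timescale_s=np.zeros(4),
                       seed=2)
        fm = generate_feature_models(spec, collinearity=0.5)
        out = orthogonalize(fm.low_visual, fm.editing)
        corr = np.abs(out.matrix.T @ fm.editing.matrix) / 300
        assert np.all(corr <= 1e-10)
        # residual variance ~ (1 - c^2) = 0.75 of the original
        ratio = out.matrix.var(axis=0) / fm.low_visual.matrix.var(axis=0)
        np.testing.assert_allclose(ratio, 0.75, atol=1e-6)

    def test_idempotent(self):
        spec = SimSpec(n_subjects_per_group=3, n_voxels=4, n_timepoints=200,
                       run_lengths=(100, 100), voxel_timescale_s=np.zeros(4),
                       seed=3)
        fm = generate_feature_models(spec, collinearity=0.4)
        once = orthogonalize(fm.high_semantic, fm.editing)
        twice = orthogonalize(once, fm.editing)
        np.testing.assert_allclose(twice.matrix, once.matrix, atol=1e-10)

    def test_rank_deficient_editing_warns(self):
        rng = np.random.default_rng(4)
        E = rng.standard_normal((60, 2))
        E = np.column_stack([E, E[:, 0] * 2.0])       # dependent column
        with pytest.warns(UserWarning, match="rank-deficient"):
            orthogonalize(feature(rng.standard_normal(60)),
                          feature(E, level="editing"))


class TestBuildDesign:
    def test_zero_column_stays_zero(self):
        model = feature(np.zeros(120), rate=0.5)
        D = build_design(model, 2.0, 120, (60, 60))
        np.testing.assert_array_equal(D[:, 0], 0.0)

    def test_impulse_gives_binned_hrf(self):
        x = np.zeros(120)
        x[0] = 1.0
        model = feature(x, rate=0.5)
        D = build_design(model, 2.0, 120, (120,), hrf=True)
        # impulse convolved with the kernel is the kernel itself sampled at TRs
        kernel = hrf_double_gamma(np.arange(0, 32.0, 2.0))
        col = D[:, 0]
        ref = np.zeros(120)
        ref[:16] = kernel
        ref = (ref - ref[:120].mean()) / ref[:120].std()
        np.testing.assert_allclose(col, ref, atol=1e-10)

    def test_boxcar_matches_convolution_oracle(self):
        rate = 5.0
        n = int(300 * rate)
        x = np.zeros(n)
        x[int(40 * rate):int(60 * rate)] = 1.0         # 20 s boxcar
        model = feature(x, times=np.arange(n) / rate, rate=rate)
        D = build_design(model, 2.0, 150, (150,), hrf=True)
        # oracle: direct numerical convolution then TR-bin averaging
        kernel = hrf_double_gamma(np.arange(0, 32.0, 1 / rate))
        conv = np.convolve(x, kernel)[:n]
        binned = conv.reshape(150, int(2 * rate)).mean(axis=1)
        ref = (binned - binned.mean()) / binned.std()
        np.testing.assert_allclose(D[:, 0], ref, atol=1e-9)

    def test_run_intercepts_appended(self):
        model = feature(np.random.default_rng(5).standard_normal(120), rate=0.5)
        D = build_design(model, 2.0, 120, (60, 60))
        assert D.shape[1] == 3
        np.testing.assert_array_equal(D[:60, 1], 1.0)
        np.testing.assert_array_equal(D[60:, 2], 1.0)

    def test_short_model_rejected(self):
        model = feature(np.zeros(50), rate=0.5)
        with pytest.raises(ValueError, match="scan"):
            build_design(model, 2.0, 120, (120,))


class TestResidualize:
    def test_intercept_only_demeans(self):
        g = make_group(seed=6)
        out = residualize_bold(g, np.ones((g.n_timepoints, 1)))
        np.testing.assert_allclose(out.data,
                                   g.data - g.data.mean(-1, keepdims=True),
                                   atol=1e-10)

    def test_series_in_span_annihilated(self):
        g = make_group(n_subjects=2, n_voxels=2, seed=7)
        rng = np.random.default_rng(7)
        X = rng.standard_normal((g.n_timepoints, 3))
        g.data[0, 0] = X @ np.array([1.0, -2.0, 0.5])
        out = residualize_bold(g, X)
        assert np.abs(out.data[0, 0]).max() < 1e-8

    def test_residuals_orthogonal_to_design(self):
        g = make_group(seed=8)
        X = np.random.default_rng(8).standard_normal((g.n_timepoints, 4))
        out = residualize_bold(g, X)
        dots = np.einsum("svt,tk->svk", out.data, X)
        assert np.abs(dots).max() < 1e-8
        # normal-equations oracle on one voxel
        Xi = np.column_stack([X, np.ones(g.n_timepoints)])
        beta = np.linalg.solve(Xi.T @ Xi, Xi.T @ g.data[0, 0])
        np.testing.assert_allclose(out.data[0, 0], g.data[0, 0] - Xi @ beta,
                                   atol=1e-8)


class TestMediatedIsc:
    def _model_driven_pair(self, seed=5):
        spec = SimSpec(n_subjects_per_group=5, n_voxels=20, n_timepoints=300,
                       run_lengths=(150, 150), voxel_timescale_s=np.zeros(20),
                       shared_amplitude=0.0, model_amplitude=1.0,
                       noise_ar1=0.0, seed=seed)
        fm = generate_feature_models(spec, collinearity=0.0)
        w = np.random.default_rng(seed).standard_normal((20, 6))
        ga, gv, truth = generate_bold_groups(spec, designs=list(fm),
                                             model_weights=w)
        D = _resampled_design(list(fm), spec)
        return ga, gv, D

    def test_intercept_only_design_no_drop(self):
        ga, gv, _ = self._model_driven_pair()
        ones = np.ones((ga.n_timepoints, 1))
        res = mediated_isc(ga, gv, ones, ones)
        assert np.abs(res.drop).max() < 1e-10

    def test_full_span_mediation(self):
        ga, gv, D = self._model_driven_pair()
        res = mediated_isc(ga, gv, D, D)
        T = ga.n_timepoints
        assert np.abs(res.isc_mediated).mean() < 2 / np.sqrt(T)
        np.testing.assert_allclose(res.drop, res.isc_original, atol=0.1)

    def test_planted_half_variance_recovered(self):
        # shared variance split half model-driven, half free; in the
        # weak-signal regime the relative drop equals the mediated
        # variance fraction (r is ~ linear in signal variance there)
        spec = SimSpec(n_subjects_per_group=5, n_voxels=20, n_timepoints=300,
                       run_lengths=(150, 150),
                       voxel_timescale_s=np.full(20, 20.0),
                       shared_amplitude=0.25, model_amplitude=0.25,
                       noise_ar1=0.0, seed=9)
        fm = generate_feature_models(spec, collinearity=0.0)
        w = np.random.default_rng(9).standard_normal((20, 6))
        ga, gv, _ = generate_bold_groups(spec, designs=list(fm), model_weights=w)
        D = _resampled_design(list(fm), spec)
        res = mediated_isc(ga, gv, D, D)
        ratio = res.drop / res.isc_original
        assert np.mean(ratio) == pytest.approx(0.5, abs=0.1)

    def test_drop_invariant_to_design_recombination(self):
        ga, gv, D = self._model_driven_pair(seed=10)
        A = np.random.default_rng(10).standard_normal((D.shape[1], D.shape[1]))
        A += np.eye(D.shape[1]) * 3              # well-conditioned invertible
        res1 = mediated_isc(ga, gv, D, D)
        res2 = mediated_isc(ga, gv, D @ A, D @ A)
        np.testing.assert_allclose(res1.drop, res2.drop, atol=1e-8)


class TestDropSignificance:
    def test_planted_mediation_detected_and_p_degenerate_case(self):
        from crossisc import drop_significance, SurrogateSpec

        # strong model-driven block of 20 voxels amid 20 null voxels
        spec = SimSpec(n_subjects_per_group=5, n_voxels=40, n_timepoints=300,
                       run_lengths=(150, 150), voxel_timescale_s=np.zeros(40),
                       shared_amplitude=0.0, model_amplitude=1.5,
                       noise_ar1=0.0, seed=20)
        fm = generate_feature_models(spec, collinearity=0.0)
        w = np.zeros((40, 6))
        w[:20] = np.random.default_rng(20).standard_normal((20, 6))
        ga, gv, _ = generate_bold_groups(spec, designs=list(fm), model_weights=w)
        D = _resampled_design(list(fm), spec)
        res = mediated_isc(ga, gv, D, D)
        out = drop_significance(res, ga, gv, D, D,
                                SurrogateSpec(n_permutations=100, seed=20))
        assert out.significant_mask[:20].mean() > 0.8
        assert out.significant_mask[20:].sum() <= 1
        assert np.nanmax(out.p_drop[20:]) > 0.05

        single = drop_significance(res, ga, gv, D, D,
                                   SurrogateSpec(n_permutations=1, seed=0))
        assert set(np.unique(single.p_drop[np.isfinite(single.p_drop)])) <= {0.5, 1.0}


def brute_force_signed_rank_p(diff):
    """Exhaustive sign-flip two-sided p for one voxel's paired differences."""
    d = diff[diff != 0]
    n = d.size
    from scipy.stats import rankdata
    ranks = rankdata(np.abs(d))
    W_obs = ranks[d > 0].sum()
    count_ge = count_le = 0
    total = 2 ** n
    for code in range(total):
        signs = 1 - 2 * ((code >> np.arange(n)) & 1)
        flipped = d * signs
        W = ranks[flipped > 0].sum()
        count_ge += W >= W_obs
        count_le += W <= W_obs
    p_hi = (1 + count_ge) / (total + 1)
    p_lo = (1 + count_le) / (total + 1)
    return min(1.0, 2 * min(p_hi, p_lo))


class TestCompareModelDrops:
    def test_identical_inputs_untestable(self):
        d = np.random.default_rng(0).standard_normal((8, 3))
        out = compare_model_drops(d, d.copy(), n_permutations=100, seed=0)
        assert np.isnan(out.W).all()

    def test_all_positive_full_rank_sum(self):
        low = np.ones((6, 2))
        high = np.zeros((6, 2))
        out = compare_model_drops(low, high, n_permutations=100, seed=1)
        np.testing.assert_array_equal(out.W, 21.0)      # 6*7/2

    def test_exact_enumeration_matches_oracle(self):
        rng = np.random.default_rng(12)
        low = rng.standard_normal((8, 4))
        high = rng.standard_normal((8, 4))
        out = compare_model_drops(low, high, seed=0, exact=True)
        for v in range(4):
            expected = brute_force_signed_rank_p(low[:, v] - high[:, v])
            assert abs(out.p[v] - expected) <= 1 / 256 + 1e-12

    def test_too_few_nonzero_flagged(self):
        low = np.zeros((6, 1))
        low[:3, 0] = 1.0
        out = compare_model_drops(low, np.zeros((6, 1)), n_permutations=50, seed=2)
        assert np.isnan(out.W[0])

    def test_signed_rank_helper(self):
        assert signed_rank_W(np.array([1.0, 2, 3, 4, 5, 6])) == 21.0
        assert np.isnan(signed_rank_W(np.array([1.0, -1, 0, 0, 0, 0])))
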