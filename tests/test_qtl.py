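"""Association testing: quantile normalization, realized relatedness, the
linear and mixed-model tests, effect sizes and their comparison."""

import numpy as np
import pytest
from scipy import stats

from germdrug import (PanelConfig, compare_qtl_effect_sizes,
                      effect_size_original_scale, kinship_eigh,
                      lm_association, lm_scan, lmm_association, lmm_scan,
                      quantile_normalize, realized_relatedness,
                      simulate_genotypes, tissue_covariates)


class TestQuantileNormalize:
    def test_two_point_values(self):
        out = quantile_normalize([5, 3, 4])  # need >= 3 obs; check order stats
        assert np.argsort(out).tolist() == np.argsort([5, 3, 4]).tolist()
        got = quantile_normalize([5.0, 3.0, 4.0])
        expected = stats.norm.ppf((np.array([3, 1, 2]) - 0.5) / 3)
        assert np.allclose(got, expected)

    def test_quartile_mapping(self):
        # ranks (2, 1) of two distinct values among n=4 duplicated pattern
        got = quantile_normalize([5.0, 3.0, 5.0, 3.0])
        # average ranks: 3.5 and 1.5 -> Phi^-1(0.75), Phi^-1(0.25)
        assert got[0] == pytest.approx(0.6745, abs=1e-4)
        assert got[1] == pytest.approx(-0.6745, abs=1e-4)

    def test_monotone_on_distinct_values(self):
        x = np.random.default_rng(0).standard_normal(100)
        y = quantile_normalize(x)
        assert np.all(np.diff(y[np.argsort(x)]) > 0)

    def test_constant_input_all_zero(self):
        with pytest.warns(UserWarning):
            assert np.all(quantile_normalize([2.0, 2.0, 2.0]) == 0)

    def test_moments_near_standard_normal(self):
        y = quantile_normalize(np.random.default_rng(1).exponential(size=500))
        assert abs(y.mean()) < 0.01
        assert 0.95 <= y.std() <= 1.05


class TestRealizedRelatedness:
    def test_single_variant_hand_computation(self):
        # dosages [0,1,2] at af 0.5: Z = [-sqrt2, 0, sqrt2], unscaled diag [2,0,2]
        K = realized_relatedness(np.array([[0.0], [1.0], [2.0]]),
                                 return_unscaled=True)
        assert np.allclose(np.diag(K), [2.0, 0.0, 2.0])
        assert K[0, 2] == pytest.approx(-2.0)

    def test_duplicate_samples(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, (5, 50)).astype(float)
        d = np.vstack([d, d[0]])  # sample 5 duplicates sample 0
        K = realized_relatedness(d)
        assert K[0, 5] == pytest.approx(K[0, 0])
        assert K[5, 5] == pytest.approx(K[0, 0])

    def test_mean_diagonal_one_and_psd(self, independent_panel):
        K = realized_relatedness(independent_panel)
        assert np.mean(np.diag(K)) == pytest.approx(1.0)
        assert np.linalg.eigvalsh(K).min() > -1e-8

    def test_subpopulation_block_structure(self):
        p = simulate_genotypes(PanelConfig(
            n_samples=200, n_variants=500, ld_block_size=1, within_block_r=0.0,
            n_subpops=2, fst_like_divergence=0.1, seed=31))
        K = realized_relatedness(p)
        same = p.samples["subpop"].to_numpy()[:, None] == \
            p.samples["subpop"].to_numpy()[None, :]
        off = ~np.eye(200, dtype=bool)
        assert K[same & off].mean() > K[~same].mean()


class TestLinearModel:
    def test_perfect_fit(self):
        x = np.array([0.0, 1.0, 2.0, 0.0, 1.0, 2.0])
        rec = lm_association(x.copy(), None, x)
        assert rec.beta == pytest.approx(1.0)
        assert rec.p_value < 1e-100

    def test_group_mean_difference(self):
        rec = lm_association([1.0, 2.0, 3.0, 4.0], None, [0.0, 0.0, 1.0, 1.0])
        assert rec.beta == pytest.approx(2.0)

    def test_null_calibration(self):
        rng = np.random.default_rng(40)
        X = rng.integers(0, 3, (200, 2000)).astype(float)
        y = rng.standard_normal(200)
        p = lm_scan(y, None, X)["p_value"].to_numpy()
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_collinear_variant_flagged(self):
        y = np.random.default_rng(4).standard_normal(20)
        W = np.repeat([0.0, 1.0], 10)
        with pytest.warns(UserWarning, match="collinear"):
            rec = lm_association(y, W, W)
        assert np.isnan(rec.p_value) and "collinear" in rec.flags

    def test_scan_matches_single(self):
        rng = np.random.default_rng(41)
        X = rng.integers(0, 3, (100, 20)).astype(float)
        W = rng.standard_normal((100, 2))
        y = rng.standard_normal(100)
        scan = lm_scan(y, W, X)
        for j in [0, 7, 19]:
            rec = lm_association(y, W, X[:, j])
            assert scan["p_value"][j] == pytest.approx(rec.p_value, rel=1e-9)
            assert scan["beta"][j] == pytest.approx(rec.beta, rel=1e-9)


class TestMixedModel:
    def test_identity_kinship_reduces_to_lm(self):
        rng = np.random.default_rng(50)
        y = rng.standard_normal(150)
        x = rng.integers(0, 3, 150).astype(float)
        W = rng.standard_normal((150, 2))
        p_lm = lm_association(y, W, x).p_value
        p_lmm = lmm_association(y, W, x, K=np.eye(150)).p_value
        assert abs(p_lm - p_lmm) < 1e-6

    def test_scan_matches_single(self, independent_panel, independent_eig):
        rng = np.random.default_rng(51)
        y = rng.standard_normal(independent_panel.n_samples)
        scan = lmm_scan(y, None, independent_panel.dosages[:, :10],
                        independent_eig)
        for j in [0, 5]:
            rec = lmm_association(y, None, independent_panel.dosages[:, j],
                                  eig=independent_eig)
            assert scan["p_value"][j] == pytest.approx(rec.p_value, rel=1e-3)

    def test_lr_statistic_nonnegative(self, independent_panel, independent_eig):
        rng = np.random.default_rng(52)
        for _ in range(5):
            y = rng.standard_normal(independent_panel.n_samples)
            x = independent_panel.dosages[:, rng.integers(0, 300)]
            rec = lmm_association(y, None, x, eig=independent_eig)
            assert rec.lr_stat >= 0.0

    def test_sample_permutation_invariance(self, independent_panel):
        rng = np.random.default_rng(53)
        n = independent_panel.n_samples
        y = rng.standard_normal(n)
        x = independent_panel.dosages[:, 0]
        W = rng.standard_normal((n, 2))
        K = realized_relatedness(independent_panel)
        rec = lmm_association(y, W, x, K=K)
        perm = rng.permutation(n)
        rec_p = lmm_association(y[perm], W[perm], x[perm],
                                K=K[np.ix_(perm, perm)])
        assert rec_p.p_value == pytest.approx(rec.p_value, rel=1e-4)
        assert rec_p.beta == pytest.approx(rec.beta, rel=1e-4)

    def test_planted_effect_recovered(self, independent_panel, independent_eig):
        rng = np.random.default_rng(54)
        x = independent_panel.dosages[:, 10]
        z = (x - x.mean()) / x.std()
        y = 0.4 * z + rng.standard_normal(independent_panel.n_samples)
        rec = lmm_association(y, None, z, eig=independent_eig)
        assert rec.p_value < 1e-10
        assert abs(rec.beta - 0.4) < 2.5 * rec.se


class TestEffectSizes:
    def test_noise_free_slope(self):
        x = np.tile([0.0, 1.0, 2.0], 10)
        y = 0.3 + 0.05 * x
        assert effect_size_original_scale(y, None, x, test_type="somatic") \
            == pytest.approx(0.05)

    def test_allele_flip_negates_beta(self):
        rng = np.random.default_rng(60)
        x = rng.integers(0, 3, 100).astype(float)
        y = 0.1 * x + rng.standard_normal(100)
        b = effect_size_original_scale(y, None, x, test_type="somatic")
        b_flip = effect_size_original_scale(y, None, 2 - x, test_type="somatic")
        assert b_flip == pytest.approx(-b)

    def test_sign_invariant_to_quantile_normalization(self):
        rng = np.random.default_rng(61)
        x = rng.integers(0, 3, 200).astype(float)
        y = 0.2 * x + rng.standard_normal(200)
        b_raw = lm_association(y, None, x).beta
        b_qn = lm_association(quantile_normalize(y), None, x).beta
        assert np.sign(b_raw) == np.sign(b_qn)


class TestEffectSizeComparison:
    def test_identical_lists(self):
        res = compare_qtl_effect_sizes([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.p_value == pytest.approx(1.0)
        assert res.mean_somatic == res.mean_germline

    def test_separated_groups(self):
        rng = np.random.default_rng(62)
        a = 0.5 + 0.01 * rng.standard_normal(50)
        b = 0.1 + 0.01 * rng.standard_normal(50)
        res = compare_qtl_effect_sizes(a, b)
        assert res.p_value < 1e-10
        assert res.mean_somatic > res.mean_germline

    def test_null_calibration(self):
        rng = np.random.default_rng(63)
        ps = [compare_qtl_effect_sizes(rng.standard_normal(20),
                                       rng.standard_normal(20)).p_value
              for _ in range(500)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_absolute_values_compared(self):
        res = compare_qtl_effect_sizes([-0.5, -0.4, -0.6], [0.1, 0.2, 0.15])
        assert res.mean_somatic == pytest.approx(0.5)


class TestTissueCovariates:
    def test_reference_level_dropped(self):
        W, levels = tissue_covariates(["a", "b", "c", "a"])
        assert W.shape == (4, 2) and levels == ["a", "b", "c"]
        # adding intercept keeps full column rank
        M = np.hstack([np.ones((4, 1)), W])
        assert np.linalg.matrix_rank(M) == 3
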