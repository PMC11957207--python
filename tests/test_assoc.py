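"""Association scan: score tests, combination rules, null model."""

import numpy as np
import pytest
from scipy.stats import chi2, kstest, norm

from fastgxe.assoc import (GxENullModel, cauchy_combine, genome_scan,
                           main_effect_test, minp_single_env_combine,
                           single_env_score_test, variance_component_test)
from fastgxe.kernels import InvalidInputError, standardize


class TestCauchyCombine:
    def test_all_half_gives_half(self):
        T, p = cauchy_combine(np.full(40, 0.5), 0.5)
        assert T == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("p_star", [1e-10, 1e-4, 0.037, 0.5, 0.81, 0.999])
    def test_single_env_identity(self, p_star):
        """q=1 with p1 = pv = p* returns p* (weights preserve one
        standard-Cauchy variate)."""
        _, p = cauchy_combine(np.array([p_star]), p_star)
        assert p == pytest.approx(p_star, rel=1e-9)

    def test_statistic_pvalue_identity(self, rng):
        for _ in range(50):
            pe = rng.uniform(1e-6, 1 - 1e-6, size=5)
            pv = float(rng.uniform(1e-6, 1 - 1e-6))
            T, p = cauchy_combine(pe, pv)
            assert abs(p - (0.5 - np.arctan(T) / np.pi)) < 1e-12

    def test_uniform_under_independent_null(self, rng):
        q, n = 7, 100_000
        pe = rng.uniform(size=(n, q))
        pv = rng.uniform(size=n)
        T = (np.tan((0.5 - pe) * np.pi).mean(axis=1)
             + np.tan((0.5 - pv) * np.pi)) / 2
        p = 0.5 - np.arctan(T) / np.pi
        assert kstest(p, "uniform").pvalue > 0.01

    def test_monotone_in_each_input(self):
        base_env = np.array([0.3, 0.6, 0.9])
        _, p0 = cauchy_combine(base_env, 0.4)
        _, p_lower = cauchy_combine(np.array([0.05, 0.6, 0.9]), 0.4)
        _, p_vc_lower = cauchy_combine(base_env, 0.04)
        assert p_lower < p0
        assert p_vc_lower < p0

    def test_nan_env_weights_renormalized(self):
        # dropping one unavailable test keeps the standard-Cauchy null
        _, p = cauchy_combine(np.array([0.2, np.nan]), 0.2)
        _, p_ref = cauchy_combine(np.array([0.2]), 0.2)
        assert p == pytest.approx(p_ref)
        assert p == pytest.approx(0.2, rel=1e-9)

    def test_empty_invalid(self):
        with pytest.raises(InvalidInputError):
            cauchy_combine(np.array([]), 0.5)

    def test_extreme_inputs_finite(self):
        T, p = cauchy_combine(np.array([1e-310, 0.5]), 1.0 - 1e-18)
        assert np.isfinite(T)
        assert 0.0 < p < 1.0


class TestMinP:
    def test_arithmetic(self):
        assert minp_single_env_combine(np.array([0.001, 0.9])) == \
            pytest.approx(0.002)
        assert minp_single_env_combine(np.ones(5)) == 1.0

    def test_median_deflation_closed_form(self, rng):
        """Median of 40*min over 40 independent uniforms equals the
        order-statistic value 40*(1 - 0.5**(1/40)) ~ 0.687."""
        p = rng.uniform(size=(40_000, 40))
        pb = np.minimum(1.0, 40 * p.min(axis=1))
        expect = 40 * (1 - 0.5 ** (1 / 40))
        assert np.median(pb) == pytest.approx(expect, abs=0.02)


class TestNullModel:
    def test_residuals_match_dense_solve(self, null_model):
        """Generalized residuals equal the direct dense solution of
        V r = y - W alpha_hat."""
        vc = null_model.vc_
        kern = null_model.kernels_
        n = null_model.n_samples_
        V = (vc.sigma_g2_ * kern.dense_grm() + vc.sigma_v2_ * kern.K_GxE
             + vc.sigma_e2_ * np.eye(n))
        y = null_model.design_.y
        W = null_model.W_
        direct = np.linalg.solve(V, y - W @ null_model.alpha_)
        assert np.abs(direct - null_model.residuals_).max() < 1e-8

    def test_residuals_orthogonal_to_covariates(self, null_model):
        assert np.abs(null_model.W_.T @ null_model.residuals_).max() < 1e-6

    def test_gamma_positive_and_near_exact_ratio(self, null_model, rng):
        assert (np.asarray(null_model.gamma_) > 0).all()
        n = null_model.n_samples_
        design = null_model.design_
        x = standardize(rng.binomial(2, 0.3, n).astype(float))
        d = x * design.X_E[:, 0]
        exact = float(d @ null_model.projected(d))
        approx = null_model.gamma_[0] * float(d @ d)
        assert abs(exact - approx) / exact < 0.1

    def test_permutation_equivariance(self, small_cohort):
        from fastgxe.kernels import KernelSet, StandardizedDesign, \
            build_kernels

        rng = np.random.default_rng(3)
        design = small_cohort["design"]
        kern = small_cohort["kernels"]
        p = rng.permutation(design.n)
        design_p = StandardizedDesign(
            sample_ids=design.sample_ids[p], y=design.y[p], X_G=None,
            X_E=design.X_E[p], W=design.W[p])
        kern_p = KernelSet(K_G=kern.dense_grm()[np.ix_(p, p)],
                           K_E=kern.K_E[np.ix_(p, p)],
                           K_GxE=kern.K_GxE[np.ix_(p, p)],
                           m_snps=kern.m_snps)
        m0 = GxENullModel(random_state=1).fit(
            design, kern, gamma_genotypes=small_cohort["X_std"])
        m1 = GxENullModel(random_state=1).fit(
            design_p, kern_p, gamma_genotypes=small_cohort["X_std"][p])
        assert np.abs(m0.residuals_[p] - m1.residuals_).max() < 1e-7
        assert np.allclose(m0.gamma_, m1.gamma_, rtol=1e-6)


class TestPerSnpTests:
    def test_strong_main_effect_detected(self, small_cohort, null_model):
        design = small_cohort["design"]
        rng = np.random.default_rng(11)
        x = standardize(design.y + 0.05 * rng.standard_normal(design.n))
        beta, p = main_effect_test(null_model, x)
        assert p < 1e-20
        assert beta != 0

    def test_monomorphic_skipped(self, null_model):
        beta, p = main_effect_test(null_model, np.zeros(null_model.n_samples_))
        assert np.isnan(beta) and np.isnan(p)

    def test_zero_variance_interaction_gives_p_one(self, null_model):
        p = single_env_score_test(null_model, np.zeros(null_model.n_samples_),
                                  0)
        assert p == 1.0

    def test_env_index_out_of_range(self, null_model, rng):
        x = standardize(rng.standard_normal(null_model.n_samples_))
        with pytest.raises(InvalidInputError):
            single_env_score_test(null_model, x, 99)

    def test_vc_matches_single_env_when_q_one(self, rng):
        """With one environment the variance-component test and the
        single-environment z-test are the same chi-square(1) statistic."""
        from fastgxe.kernels import build_kernels
        from tests.conftest import make_design

        n = 1000
        design = make_design(n, 1, rng)
        X_G = standardize(rng.binomial(2, 0.4, size=(n, 300)).astype(float))
        kern = build_kernels(X_G, design.X_E)
        null = GxENullModel(random_state=0).fit(design, kern,
                                                gamma_genotypes=X_G)
        for j in range(5):
            x = X_G[:, j]
            p1 = single_env_score_test(null, x, 0)
            pv = variance_component_test(null, x)
            if min(p1, pv) > 1e-12:
                assert abs(np.log10(p1) - np.log10(pv)) < 0.1

    def test_degenerate_genotype_vc(self, null_model):
        p = variance_component_test(null_model,
                                    np.zeros(null_model.n_samples_))
        assert p == 1.0


class TestGenomeScan:
    def test_completeness_all_modes(self, small_cohort, null_model):
        design = small_cohort["design"]
        kern = small_cohort["kernels"]
        dos = small_cohort["geno"].dosages[:, :200]
        for mode in ("fastgxe", "minp", "vc_only_nopoly"):
            res = genome_scan(design, kern, dos, mode=mode, null=null_model)
            assert len(res) == 200
            ok = res["qc_pass"]
            p = res.loc[ok, "p_gxe"]
            assert ((p > 0) & (p <= 1)).all()

    def test_statistic_identity_in_output(self, small_cohort, null_model):
        res = genome_scan(small_cohort["design"], small_cohort["kernels"],
                          small_cohort["geno"].dosages[:, :80],
                          mode="fastgxe", null=null_model)
        ok = res["qc_pass"] & (res["T"].abs() < 1e10)
        expect = 0.5 - np.arctan(res.loc[ok, "T"]) / np.pi
        assert np.abs(expect - res.loc[ok, "p_gxe"]).max() < 1e-12

    def test_beta_main_zeroed_by_prefilter(self, small_cohort, null_model):
        res = genome_scan(small_cohort["design"], small_cohort["kernels"],
                          small_cohort["geno"].dosages[:, :300],
                          mode="fastgxe", null=null_model)
        weak = res["p_main"] > 1e-3
        assert (res.loc[weak, "beta_main"] == 0.0).all()
        strong = (res["p_main"] <= 1e-3) & res["qc_pass"]
        if strong.any():
            assert (res.loc[strong, "beta_main"] != 0.0).all()

    def test_sample_mismatch_raises(self, small_cohort, null_model):
        with pytest.raises(InvalidInputError):
            genome_scan(small_cohort["design"], small_cohort["kernels"],
                        small_cohort["geno"].dosages[:100], null=null_model)

    def test_injected_gxe_ranks_first(self, rng):
        """A SNP with a strong interaction tops the combined-test ranking."""
        from fastgxe.kernels import StandardizedDesign, build_kernels

        n, m, q = 800, 300, 8
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(
            float)
        X_G = standardize(dos)
        X_E = standardize(rng.standard_normal((n, q)))
        target = 42
        gxe = X_G[:, target] * X_E[:, 0]
        y = standardize(gxe * np.sqrt(0.05 / gxe.var())
                        + rng.standard_normal(n))
        design = StandardizedDesign(sample_ids=np.arange(n), y=y, X_G=None,
                                    X_E=X_E, W=np.ones((n, 1)))
        kern = build_kernels(X_G, X_E)
        res = genome_scan(design, kern, dos, mode="fastgxe",
                          random_state=0)
        assert int(res["p_gxe"].idxmin()) == target

    def test_unknown_mode(self, small_cohort):
        with pytest.raises(InvalidInputError):
            genome_scan(small_cohort["design"], small_cohort["kernels"],
                        small_cohort["geno"].dosages[:, :10], mode="bogus")
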