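"""Environment selection: whitening and sum-of-single-effects regression."""

import numpy as np
import pytest
from sklearn.base import clone

from fastgxe.envselect import (SusieRegression, residualize_main,
                               select_environments, susie_ibss, whiten)
from fastgxe.kernels import standardize


class TestResidualize:
    def test_exact_multiple_gives_zero(self, rng):
        x = standardize(rng.standard_normal(50))
        assert np.abs(residualize_main(2.0 * x, x)).max() < 1e-10

    def test_orthogonal_unchanged(self, rng):
        x = standardize(rng.standard_normal(200))
        y = rng.standard_normal(200)
        y -= y.mean()
        y -= x * (x @ y) / (x @ x)
        out = residualize_main(y, x)
        assert np.abs(out - y).max() < 1e-10

    def test_projection_orthogonality(self, rng):
        x = standardize(rng.standard_normal(120))
        y = rng.standard_normal(120)
        assert abs(x @ residualize_main(y, x)) < 1e-9


class _FakeNull:
    def __init__(self, vc, kernels):
        self.vc_ = vc
        self.kernels_ = kernels


class _FakeVc:
    def __init__(self, g, v, e):
        self.sigma_g2_, self.sigma_v2_, self.sigma_e2_ = g, v, e


class TestWhiten:
    def _kernels(self, rng, n):
        from fastgxe.kernels import build_kernels

        X_G = standardize(rng.standard_normal((n, 2 * n)))
        X_E = standardize(rng.standard_normal((n, 4)))
        return build_kernels(X_G, X_E)

    def test_iid_limit_is_scalar_scaling(self, rng):
        n = 40
        kern = self._kernels(rng, n)
        null = _FakeNull(_FakeVc(0.0, 0.0, 4.0), kern)
        X = rng.standard_normal((n, 3))
        y = rng.standard_normal(n)
        X_w, y_w = whiten(null, X, y)
        assert np.allclose(X_w, X / 2.0)
        assert np.allclose(y_w, y / 2.0)

    def test_double_whitening_consistency(self, rng):
        n = 60
        kern = self._kernels(rng, n)
        vc = _FakeVc(0.5, 0.2, 0.3)
        Sigma = (0.5 * kern.dense_grm() + 0.2 * kern.K_GxE
                 + 0.3 * np.eye(n))
        null = _FakeNull(vc, kern)
        X_w, _ = whiten(null, Sigma, np.zeros(n))
        # whiten applies Sigma^{-1/2}; applying it twice to Sigma gives I
        half, _ = whiten(null, X_w, np.zeros(n))
        assert np.abs(half - np.eye(n)).max() < 1e-8

    def test_equivalent_to_gls(self, rng):
        n = 200
        kern = self._kernels(rng, n)
        vc = _FakeVc(0.4, 0.1, 0.5)
        Sigma = (0.4 * kern.dense_grm() + 0.1 * kern.K_GxE
                 + 0.5 * np.eye(n))
        null = _FakeNull(vc, kern)
        X = rng.standard_normal((n, 5))
        y = rng.standard_normal(n)
        X_w, y_w = whiten(null, X, y)
        beta_w = np.linalg.lstsq(X_w, y_w, rcond=None)[0]
        Si = np.linalg.inv(Sigma)
        beta_gls = np.linalg.solve(X.T @ Si @ X, X.T @ Si @ y)
        assert np.allclose(beta_w, beta_gls, atol=1e-8)


class TestSusie:
    def test_single_strong_environment_recovered(self):
        """A lone z~5 environment gets PIP > 0.95 in every replicate;
        the other 39 stay below 0.05 in the typical replicate (an
        occasional spurious secondary effect can lift one of them to a
        moderate, still sub-threshold value)."""
        clean = strong = 0
        for seed in range(5):
            g = np.random.default_rng(2024 + seed)
            n, q = 1000, 40
            X = standardize(g.standard_normal((n, q)))
            beta = 5.0 / np.sqrt(n)      # z ~ 5 signal
            y = X[:, 7] * beta + g.standard_normal(n)
            model = SusieRegression(L=10).fit(X, y)
            others = np.delete(model.pip_, 7)
            assert others.max() < 0.5
            strong += model.pip_[7] > 0.95
            clean += others.max() < 0.05
        assert strong >= 4
        assert clean >= 3

    def test_pure_noise_keeps_pips_small(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(500 + rep)
            X = standardize(rng.standard_normal((400, 20)))
            y = rng.standard_normal(400)
            model = SusieRegression(L=10).fit(X, y)
            hits += model.pip_.max() < 0.5
        assert hits >= 18

    def test_elbo_monotone(self, rng):
        X = standardize(rng.standard_normal((300, 15)))
        y = X[:, 2] * 0.3 + X[:, 9] * 0.2 + rng.standard_normal(300)
        model = SusieRegression(L=5).fit(X, y)
        diffs = np.diff(model.elbo_)
        assert (diffs > -1e-6).all()

    def test_single_variable_pip_is_one(self, rng):
        """With one variable and a fixed prior the inclusion vector is
        trivially concentrated (alpha sums to one over one variable)."""
        X = standardize(rng.standard_normal((100, 1)))
        y = 0.5 * X[:, 0] + rng.standard_normal(100)
        model = SusieRegression(L=1, estimate_prior_variance=False).fit(X, y)
        assert model.pip_[0] == pytest.approx(1.0)
        assert model.alpha_[0].sum() == pytest.approx(1.0)

    def test_ser_matches_closed_form_bayes_factors(self, rng):
        """L=1 with fixed prior equals the analytic single-effect
        regression posterior."""
        n, q = 150, 6
        X = standardize(rng.standard_normal((n, q)))
        y = X[:, 3] * 0.4 + rng.standard_normal(n)
        s0 = 0.25
        s2 = float(np.var(y))   # the model initializes sigma2 at var(y)
        model = SusieRegression(
            L=1, prior_variance=s0, estimate_prior_variance=False,
            estimate_residual_variance=False, max_iter=1, tol=-1).fit(X, y)
        # independent closed form
        d = (X ** 2).sum(axis=0)
        bhat = X.T @ y / d
        shat2 = s2 / d
        log_bf = (0.5 * np.log(shat2 / (shat2 + s0))
                  + 0.5 * bhat ** 2 / shat2 * s0 / (shat2 + s0))
        w = np.exp(log_bf - log_bf.max())
        alpha = w / w.sum()
        assert np.allclose(model.alpha_[0], alpha, atol=1e-10)
        mu = s0 / (s0 + shat2) * bhat
        assert np.allclose(model.mu_[0], mu, atol=1e-10)

    def test_two_signals_credible_sets(self, rng):
        n, q = 800, 30
        X = standardize(rng.standard_normal((n, q)))
        y = 0.35 * X[:, 4] + 0.3 * X[:, 21] + rng.standard_normal(n)
        model = SusieRegression(L=10).fit(X, y)
        members = sorted(int(m) for cs in model.credible_sets_
                         for m in cs["members"] if cs["coverage"] >= 0.9)
        assert 4 in members and 21 in members

    def test_sklearn_interface(self, rng):
        model = SusieRegression(L=3, tol=1e-3)
        cloned = clone(model)
        assert cloned.get_params()["L"] == 3
        X = standardize(rng.standard_normal((50, 4)))
        y = rng.standard_normal(50)
        model.fit(X, y)
        assert model.predict(X).shape == (50,)


class TestPipeline:
    def test_select_environments_full_path(self, small_cohort, null_model):
        """End-to-end: residualize, whiten by the fitted covariance, and
        select; a planted interaction environment is found."""
        rng = np.random.default_rng(21)
        design = small_cohort["design"]
        X_std = small_cohort["X_std"]
        x = X_std[:, 5]
        gxe = x * design.X_E[:, 2]
        y_new = standardize(design.y * 0.6
                            + gxe * np.sqrt(0.35 / gxe.var()))
        design2 = type(design)(sample_ids=design.sample_ids, y=y_new,
                               X_G=None, X_E=design.X_E, W=design.W)
        null2 = type(null_model)(random_state=0).fit(
            design2, small_cohort["kernels"],
            gamma_genotypes=small_cohort["X_std"])
        sel = select_environments(null2, x, snp_id="snp5", L=5)
        assert 2 in sel.selected
        assert sel.pip[2] > 0.9
        assert sel.b_gxe_post.shape == (design.X_E.shape[1],)

    def test_susie_ibss_wrapper_packaging(self, rng):
        X = standardize(rng.standard_normal((200, 10)))
        y = X[:, 1] * 0.8 + rng.standard_normal(200) * 0.5
        sel = susie_ibss(X, y, L=4, snp_id="rs1")
        assert sel.snp_id == "rs1"
        assert sel.pip.shape == (10,)
        assert (sel.pip >= 0).all() and (sel.pip <= 1).all()
        assert set(sel.selected) == set(np.flatnonzero(sel.pip > 0.5))
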