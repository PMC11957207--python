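"""Which environments drive a detected GxE signal?

A significant combined test says a SNP interacts with *some* of the q
environments; this module identifies which ones.  The interaction
effects are modeled with a sum-of-single-effects (SuSiE) prior,

    y_tilde = X_GxE b + g + v + e,      b = sum_l b_l,
    b_l = gamma_l beta_l,  gamma_l ~ Mult(1, pi),  beta_l ~ N(0, s0l^2),

where ``y_tilde`` is the trait with the marginal SNP effect regressed
out and ``X_GxE = diag(x_G) X_E``.  The polygenic (g) and polygenic
interaction (v) random effects are absorbed by whitening: with
``Sigma = sigma_g^2 K_G + sigma_v^2 K_GxE + sigma_e^2 I`` the
transformed regression of ``Sigma^{-1/2} y_tilde`` on
``Sigma^{-1/2} X_GxE`` is an ordinary SuSiE problem, fitted by iterative
Bayesian single-effect (IBSS) coordinate ascent with an evidence lower
bound that is non-decreasing per sweep.

Environments with posterior inclusion probability PIP > 0.5 are declared
drivers of the interaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .kernels import InvalidInputError

PIP_THRESHOLD = 0.5


@dataclass
class EnvSelection:
    """Per-SNP environment-selection result."""

    snp_id: str
    pip: np.ndarray
    b_gxe_post: np.ndarray
    credible_sets: list[dict] = field(default_factory=list)
    selected: np.ndarray = field(default_factory=lambda: np.array([], int))
    L: int = 10
    converged: bool = True


def residualize_main(y: np.ndarray, x_G: np.ndarray) -> np.ndarray:
    """Remove the marginal SNP effect (and intercept) from the trait."""
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x_G, dtype=np.float64)
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def whiten(null, X_GxE: np.ndarray, y_tilde: np.ndarray):
    """Transform the mixed model to homoscedastic regression.

    ``null`` is a fitted :class:`~fastgxe.assoc.GxENullModel` (or any
    object with ``vc_`` and ``kernels_``).  Uses the symmetric eigen
    square root of Sigma; a near-singular Sigma gets a 1e-8 ridge with a
    warning.
    """
    vc = null.vc_
    kern = null.kernels_
    K_G = kern.dense_grm()
    Sigma = vc.sigma_g2_ * K_G + vc.sigma_v2_ * kern.K_GxE
    Sigma[np.diag_indices_from(Sigma)] += vc.sigma_e2_
    w, U = np.linalg.eigh(Sigma)
    if w[0] < 1e-8 * w[-1]:
        warnings.warn("near-singular covariance; adding 1e-8 ridge",
                      UserWarning, stacklevel=2)
        w = w + 1e-8 * w[-1]
    inv_sqrt = U * (1.0 / np.sqrt(w))[None, :]
    X_w = inv_sqrt @ (U.T @ X_GxE)
    y_w = inv_sqrt @ (U.T @ y_tilde)
    return X_w, y_w


def _ser_update(X, r, sigma2, prior_var, d, pi, optimize_prior,
                null_threshold=0.1):
    """One single-effect regression update; returns (alpha, mu, tau, s0)."""
    Xtr = X.T @ r
    bhat = Xtr / d
    shat2 = sigma2 / d

    def neg_loglik(log_s0):
        s0 = np.exp(log_s0)
        log_bf = (0.5 * np.log(shat2 / (shat2 + s0))
                  + 0.5 * bhat ** 2 / shat2 * (s0 / (shat2 + s0)))
        m = log_bf.max()
        return -(m + np.log(np.sum(pi * np.exp(log_bf - m))))

    s0 = prior_var
    if optimize_prior:
        # empirical-Bayes prior variance: maximize the SER marginal
        # likelihood, and switch the effect off (s0 = 0) unless the
        # optimum beats the null model by the check threshold (in nats)
        res = minimize_scalar(neg_loglik, bounds=(-30.0, 10.0),
                              method="bounded",
                              options={"xatol": 1e-8})
        s0 = float(np.exp(res.x)) if -res.fun > null_threshold else 0.0
    if s0 > 0:
        log_bf = (0.5 * np.log(shat2 / (shat2 + s0))
                  + 0.5 * bhat ** 2 / shat2 * (s0 / (shat2 + s0)))
        m = log_bf.max()
        w = pi * np.exp(log_bf - m)
        alpha = w / w.sum()
        tau = s0 * shat2 / (s0 + shat2)
        mu = (s0 / (s0 + shat2)) * bhat
    else:
        alpha = pi.copy()
        mu = np.zeros_like(bhat)
        tau = np.zeros_like(bhat)
    return alpha, mu, tau, s0


class SusieRegression(BaseEstimator, RegressorMixin):
    """Sum-of-single-effects regression (SuSiE) via IBSS.

    A scikit-learn style estimator: ``fit(X, y)`` runs iterative Bayesian
    single-effect coordinate ascent; fitted attributes carry posterior
    inclusion probabilities, posterior means, and credible sets.

    Parameters
    ----------
    L : int
        Number of single effects.
    prior_variance : float
        Initial prior effect variance (per effect); optimized per effect
        by empirical Bayes when ``estimate_prior_variance``.
    estimate_prior_variance, estimate_residual_variance : bool
        Empirical-Bayes updates for the effect prior and the residual
        variance.
    check_null_threshold : float
        Minimum gain (nats) of the optimized single-effect marginal
        likelihood over the null before an effect is kept; effects
        below it get prior variance zero and are excluded from PIPs.
    max_iter, tol : IBSS stopping rule (ELBO change below ``tol``).
    coverage, purity : credible-set coverage level and minimum absolute
        correlation for purity pruning.

    Attributes
    ----------
    pip_ : (p,) posterior inclusion probabilities, 1 - prod_l(1-alpha_lj)
    coef_ : (p,) posterior mean effects sum_l alpha_lj mu_lj
    alpha_, mu_, tau_ : (L, p) per-effect posteriors
    elbo_ : per-iteration evidence lower bound (non-decreasing)
    credible_sets_ : list of dicts with keys "members", "coverage", "purity"
    """

    def __init__(self, L: int = 10, prior_variance: float = 0.2,
                 estimate_prior_variance: bool = True,
                 estimate_residual_variance: bool = True,
                 check_null_threshold: float = 0.1,
                 max_iter: int = 200, tol: float = 1e-4,
                 coverage: float = 0.95, purity: float = 0.5):
        self.L = L
        self.prior_variance = prior_variance
        self.estimate_prior_variance = estimate_prior_variance
        self.estimate_residual_variance = estimate_residual_variance
        self.check_null_threshold = check_null_threshold
        self.max_iter = max_iter
        self.tol = tol
        self.coverage = coverage
        self.purity = purity

    def fit(self, X: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        n, p = X.shape
        if self.L < 1:
            raise InvalidInputError("L must be >= 1")
        d = np.einsum("ij,ij->j", X, X)
        if np.any(d <= 0):
            raise InvalidInputError("X contains an all-zero column")
        L = min(self.L, p)
        pi = np.full(p, 1.0 / p)
        alpha = np.full((L, p), 1.0 / p)
        mu = np.zeros((L, p))
        tau = np.zeros((L, p))
        s0 = np.full(L, self.prior_variance)
        sigma2 = float(np.var(y)) or 1.0
        Xb_l = np.zeros((L, n))            # per-effect fitted values
        Xb = np.zeros(n)
        elbo_hist: list[float] = []
        converged = False
        for it in range(self.max_iter):
            for l in range(L):
                r = y - (Xb - Xb_l[l])
                alpha[l], mu[l], tau[l], s0[l] = _ser_update(
                    X, r, sigma2, s0[l] or self.prior_variance, d, pi,
                    self.estimate_prior_variance,
                    self.check_null_threshold)
                Xb = Xb - Xb_l[l]
                Xb_l[l] = X @ (alpha[l] * mu[l])
                Xb = Xb + Xb_l[l]
            erss = self._erss(X, y, Xb, Xb_l, alpha, mu, tau, d)
            if self.estimate_residual_variance:
                sigma2 = erss / n
            elbo = self._elbo(n, sigma2, erss, alpha, mu, tau, s0, pi)
            elbo_hist.append(elbo)
            if it > 0 and abs(elbo_hist[-1] - elbo_hist[-2]) < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn("IBSS did not converge; returning best fit",
                          UserWarning, stacklevel=2)
        self.alpha_, self.mu_, self.tau_ = alpha, mu, tau
        self.prior_variance_ = s0
        self.sigma2_ = sigma2
        # effects whose prior variance collapsed carry no signal; their
        # uniform alpha must not leak into the inclusion probabilities
        live = s0 > 1e-9
        if live.any():
            self.pip_ = 1.0 - np.prod(1.0 - alpha[live], axis=0)
        else:
            self.pip_ = np.zeros(p)
        self.coef_ = np.sum(alpha * mu, axis=0)
        self.elbo_ = np.asarray(elbo_hist)
        self.converged_ = converged
        self.credible_sets_ = self._credible_sets(X, alpha, s0)
        self.n_features_in_ = p
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=np.float64) @ self.coef_

    @staticmethod
    def _erss(X, y, Xb, Xb_l, alpha, mu, tau, d):
        """Expected residual sum of squares under the posterior."""
        resid = y - Xb
        post2 = alpha * (mu ** 2 + tau)    # E[b_lj^2]
        return (float(resid @ resid)
                - float(np.sum(Xb_l ** 2))
                + float(np.sum(post2 * d[None, :])))

    @staticmethod
    def _elbo(n, sigma2, erss, alpha, mu, tau, s0, pi):
        loglik = -0.5 * n * np.log(2 * np.pi * sigma2) - erss / (2 * sigma2)
        kl = 0.0
        for l in range(alpha.shape[0]):
            a = alpha[l]
            nz = a > 1e-300
            kl += float(np.sum(a[nz] * np.log(a[nz] / pi[nz])))
            with np.errstate(divide="ignore", invalid="ignore"):
                kl_b = 0.5 * (np.log(s0[l] / np.maximum(tau[l], 1e-300))
                              + (tau[l] + mu[l] ** 2) / s0[l] - 1.0)
            kl += float(np.sum(a[nz] * kl_b[nz])) if s0[l] > 0 else 0.0
        return loglik - kl

    def _credible_sets(self, X, alpha, s0):
        sets = []
        Xc = X - X.mean(axis=0)
        norm = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
        norm[norm == 0] = 1.0
        for l in range(alpha.shape[0]):
            if s0[l] < 1e-9:           # effect switched off
                continue
            order = np.argsort(alpha[l])[::-1]
            csum = np.cumsum(alpha[l][order])
            k = int(np.searchsorted(csum, self.coverage)) + 1
            members = np.sort(order[:k])
            if members.size > 1:
                sub = Xc[:, members] / norm[members]
                corr = np.abs(sub.T @ sub)
                purity = float(corr[np.triu_indices_from(corr, 1)].min())
            else:
                purity = 1.0
            if purity >= self.purity:
                sets.append({"members": members,
                             "coverage": float(csum[k - 1]),
                             "purity": purity})
        return sets


def susie_ibss(X_w: np.ndarray, y_w: np.ndarray, L: int = 10,
               prior_variance: float = 0.2, max_iter: int = 200,
               tol: float = 1e-4, snp_id: str = "") -> EnvSelection:
    """Fit SuSiE on whitened data and package an :class:`EnvSelection`."""
    model = SusieRegression(L=L, prior_variance=prior_variance,
                            max_iter=max_iter, tol=tol).fit(X_w, y_w)
    pip = model.pip_
    return EnvSelection(
        snp_id=snp_id, pip=pip, b_gxe_post=model.coef_,
        credible_sets=model.credible_sets_,
        selected=np.flatnonzero(pip > PIP_THRESHOLD),
        L=L, converged=model.converged_)


def select_environments(null, x_G: np.ndarray, snp_id: str = "",
                        L: int = 10, **susie_kwargs) -> EnvSelection:
    """Full environment-selection pipeline for one SNP.

    Residualizes the trait on the SNP, whitens by the null-model
    covariance, and runs the sum-of-single-effects selection over the q
    interaction predictors.
    """
    design = null.design_
    y_tilde = residualize_main(design.y, x_G)
    X_GxE = x_G[:, None] * design.X_E
    X_w, y_w = whiten(null, X_GxE, y_tilde)
    return susie_ibss(X_w, y_w, L=L, snp_id=snp_id, **susie_kwargs)
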