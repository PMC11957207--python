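"""Genome-wide multi-environment GxE scan.

The scan is a two-step mixed-model procedure.  A null model with
polygenic (K_G) and polygenic-interaction (K_GxE) random effects plus
fixed covariates (intercept, user covariates, and the environmental main
effects) is fitted once; its generalized residuals ``r = P y`` and
per-environment variance-ratio calibration factors ``gamma_k`` are then
reused for every SNP (the GRAMMAR-GAMMA device).  Per SNP, three ingredients are
computed:

* q single-environment interaction score tests of the predictors
  ``d_k = x_G * x_E(k)`` (p_1..p_q);
* a variance-component score test treating the q interaction effects as
  random, with a weighted-chi-square null distribution (p_v);
* their aggregation into one p-value by the Cauchy combination rule

      T = 1/2 sum_k (1/q) tan((0.5 - p_k) pi) + 1/2 tan((0.5 - p_v) pi),
      p = 0.5 - arctan(T) / pi,

  which is valid under arbitrary dependence of the component p-values.

SNPs with a significant main effect (p_main <= 1e-3) are conditioned on
their own genotype as an extra fixed covariate; for the rest the
marginal effect is fixed at zero, which removes a per-SNP refit.

Two comparator strategies are provided as scan modes: ``minp``
(Bonferroni-adjusted minimum over the q single-environment tests, the
single-environment mixed-model strategy) and ``vc_only_nopoly`` (the
multi-environment variance-component test with environment fixed effects
but no polygenic or polygenic-interaction random effects).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse as sp
from scipy import special
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

from ._quadform import wchi2_sf, wchi2_sf_batch
from .kernels import InvalidInputError, KernelSet, StandardizedDesign
from .varcomp import MoMVarianceComponents

MAIN_EFFECT_FILTER_P = 1e-3  # below this, condition on the SNP main effect
P_CLIP_LO = 1e-300           # clipping bounds before the tangent transform
P_CLIP_HI = 1.0 - 1e-16


def _p_from_z(z: np.ndarray) -> np.ndarray:
    return special.erfc(np.abs(z) / np.sqrt(2.0))


def _cauchy_tail(T: np.ndarray | float) -> np.ndarray | float:
    """p = 0.5 - arctan(T)/pi, evaluated stably for |T| large."""
    T = np.asarray(T, dtype=np.float64)
    p = np.where(
        T > 1.0, np.arctan2(1.0, T) / np.pi,
        np.where(T < -1.0, 1.0 - np.arctan2(1.0, -T) / np.pi,
                 0.5 - np.arctan(T) / np.pi))
    return p if p.ndim else float(p)


class GxENullModel(BaseEstimator):
    """Null mixed model shared by all per-SNP tests.

    Fits variance components by method of moments, then precomputes the
    generalized residual vector, the covariate projections, and the
    GRAMMAR-GAMMA calibration factors.

    Parameters
    ----------
    n_gamma_predictors : int
        Total number of random interaction predictors used to estimate
        the per-environment calibration factors
        gamma_k = mean(d' P d / d' M0 d) (M0 projects out the fixed
        covariates).
    s, exact_traces, random_state : passed to the MoM component fit.

    Attributes
    ----------
    vc_ : fitted MoMVarianceComponents
    residuals_ : generalized residuals V^-1 (y - W alpha_hat) = P y
    gamma_ : (q,) per-environment calibration factors for interaction
        predictors
    gamma_main_ : calibration factor for genotype main-effect predictors
    alpha_ : covariate effect estimates (GLS)
    """

    def __init__(self, n_gamma_predictors: int = 500, s: int = 30,
                 exact_traces: bool | str = "auto",
                 random_state: int | None = None):
        self.n_gamma_predictors = n_gamma_predictors
        self.s = s
        self.exact_traces = exact_traces
        self.random_state = random_state

    def fit(self, design: StandardizedDesign, kernels: KernelSet,
            gamma_genotypes: np.ndarray | None = None):
        y = design.y
        n = y.shape[0]
        if kernels.K_E.shape[0] != n:
            raise InvalidInputError("kernels and design sample sizes differ")
        K_G = kernels.dense_grm()
        K_X = kernels.K_GxE
        W = np.column_stack([design.W, design.X_E])

        vc = MoMVarianceComponents(
            s=self.s, exact_traces=self.exact_traces,
            random_state=self.random_state,
        ).fit(y, K_G, K_X, W=W)

        V = vc.sigma_g2_ * K_G + vc.sigma_v2_ * K_X
        V[np.diag_indices_from(V)] += vc.sigma_e2_
        try:
            chol = cho_factor(V, lower=True, check_finite=False)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - diagnostic
            eig_min = float(np.linalg.eigvalsh(V)[0])
            raise np.linalg.LinAlgError(
                f"null covariance not positive definite "
                f"(min eigenvalue {eig_min:.3e})") from exc

        ViW = cho_solve(chol, W, check_finite=False)
        WtViW = W.T @ ViW
        alpha = np.linalg.solve(WtViW, ViW.T @ y)
        r = cho_solve(chol, y - W @ alpha, check_finite=False)

        rng = np.random.default_rng(self.random_state)
        X_G = gamma_genotypes
        if X_G is None and design.X_G is not None:
            X_G = design.X_G
        WtViW_inv = np.linalg.inv(WtViW)
        Q0, _ = np.linalg.qr(W)        # orthonormal covariate basis

        def _proj_quad(D):
            # ratio of the exact score variance d'Pd (P = V^-1 - V^-1 W
            # (W'V^-1 W)^-1 W'V^-1) to the covariate-projected Euclidean
            # norm d'M0 d.  Using M0 rather than the raw d'd matters:
            # with ~q covariates the per-predictor covariate alignment
            # fluctuates by O(sqrt(c)/n), and leaving it in the
            # denominator residual breaks the score-test approximation
            # at moderate n
            ViD = cho_solve(chol, D, check_finite=False)
            WtViD = ViW.T @ D
            quad = (np.sum(D * ViD, axis=0)
                    - np.sum(WtViD * (WtViW_inv @ WtViD), axis=0))
            QtD = Q0.T @ D
            m0 = np.sum(D * D, axis=0) - np.sum(QtD * QtD, axis=0)
            return quad / m0

        q = design.X_E.shape[1]
        if X_G is not None and X_G.shape[1] > 0:
            # one calibration factor per environment: the variance ratio
            # d'Pd/d'd differs systematically across environments
            # (skew/kurtosis of x_E enters d = x_G * x_E), and a single
            # pooled factor leaves per-environment z-scores off by
            # several percent
            per_env = max(8, self.n_gamma_predictors // q)
            gammas = np.empty(q)
            for k in range(q):
                cols = rng.integers(0, X_G.shape[1], size=per_env)
                D = X_G[:, cols] * design.X_E[:, [k]]
                gammas[k] = float(np.mean(_proj_quad(D)))
            self.gamma_ = gammas
            k2 = min(self.n_gamma_predictors, X_G.shape[1])
            cols = rng.choice(X_G.shape[1], size=k2, replace=False)
            self.gamma_main_ = float(np.mean(_proj_quad(X_G[:, cols])))
        else:
            # no genotypes for calibration: fall back to the spectral mean
            spectral = float(np.mean(1.0 / np.linalg.eigvalsh(V)))
            self.gamma_ = np.full(q, spectral)
            self.gamma_main_ = spectral

        self.vc_ = vc
        self.residuals_ = r
        self.alpha_ = alpha
        self.W_ = W
        self._Q0 = Q0
        self._chol = chol
        self._ViW = ViW
        self._WtViW_inv = WtViW_inv
        self.n_samples_ = n
        self.design_ = design
        self.kernels_ = kernels
        return self

    def v_inv(self, B: np.ndarray) -> np.ndarray:
        """Apply V^-1 to a vector or matrix."""
        return cho_solve(self._chol, B, check_finite=False)

    def m0_norm2(self, d: np.ndarray) -> float:
        """Squared norm of d after projecting out the fixed covariates."""
        t = self._Q0.T @ d
        return float(d @ d - t @ t)

    def m0(self, d: np.ndarray) -> np.ndarray:
        """Project the fixed covariates out of d (Euclidean metric)."""
        return d - self._Q0 @ (self._Q0.T @ d)

    def projected(self, x: np.ndarray) -> np.ndarray:
        """Apply the null projection P = V^-1 - V^-1 W (W'V^-1 W)^-1 W'V^-1."""
        Vx = self.v_inv(x)
        return Vx - self._ViW @ (self._WtViW_inv @ (self._ViW.T @ x))

    def condition_on(self, x: np.ndarray):
        """Residuals and projector direction after adding x as a covariate.

        Returns ``(r_new, u, xtu)`` with ``u = P x`` so that
        ``P_new y = r - u (x' r) / (x' u)``.
        """
        u = self.projected(x)
        xtu = float(x @ u)
        if xtu <= 0:
            raise InvalidInputError("conditioning covariate is degenerate")
        r_new = self.residuals_ - u * (float(x @ self.residuals_) / xtu)
        return r_new, u, xtu


def fit_null_model(design: StandardizedDesign, kernels: KernelSet,
                   **kwargs) -> GxENullModel:
    """Fit the shared null mixed model (see :class:`GxENullModel`)."""
    return GxENullModel(**kwargs).fit(design, kernels)


def main_effect_test(null: GxENullModel, x_G: np.ndarray):
    """GRAMMAR-GAMMA score test of the SNP main effect beta_G.

    Returns ``(beta, p_main)``; downstream interaction tests condition on
    the genotype only when ``p_main <= 1e-3``.
    """
    x = np.asarray(x_G, dtype=np.float64)
    ss = float(x @ x)
    if ss <= 0:
        return np.nan, np.nan
    U = float(x @ null.residuals_)
    var = null.gamma_main_ * ss
    beta = U / var
    z = U / np.sqrt(var)
    return beta, float(_p_from_z(np.array(z)))


def single_env_score_test(null: GxENullModel, x_G: np.ndarray,
                          env_index: int,
                          condition_main: bool = False) -> float:
    """Score test of the interaction predictor ``d = x_G * x_E(k)``."""
    X_E = null.design_.X_E
    if not 0 <= env_index < X_E.shape[1]:
        raise InvalidInputError(f"env_index {env_index} out of range")
    d = x_G * X_E[:, env_index]
    if float(d @ d) <= 0:
        return 1.0
    r = null.residuals_
    if condition_main:
        r, _, _ = null.condition_on(x_G)
        xm = null.m0(x_G)
        ss = null.m0_norm2(d) - float(xm @ d) ** 2 / float(xm @ xm)
        if ss <= 1e-12:
            return 1.0
    else:
        ss = null.m0_norm2(d)
        if ss <= 0:
            return 1.0
    U = float(d @ r)
    z = U / np.sqrt(null.gamma_[env_index] * ss)
    return float(_p_from_z(np.array(z)))


def variance_component_test(null: GxENullModel, x_G: np.ndarray,
                            X_E: np.ndarray | None = None,
                            condition_main: bool = False) -> float:
    """Variance-component score test of all q interactions jointly.

    The statistic is ``Q = r' G G' r`` with ``G = diag(x_G) X_E / sqrt(q)``
    and null distribution ``sum_k lambda_k chi2_1`` where the weights are
    the eigenvalues of ``gamma G'G`` (the GRAMMAR-GAMMA approximation to
    ``G'PG``).
    """
    if X_E is None:
        X_E = null.design_.X_E
    q = X_E.shape[1]
    if q < 1:
        raise InvalidInputError("variance-component test needs q >= 1")
    if float(x_G @ x_G) <= 0:
        return 1.0
    G = (x_G[:, None] * X_E) / np.sqrt(q)
    r = null.residuals_
    Gp = G - null._Q0 @ (null._Q0.T @ G)
    if condition_main:
        r, _, _ = null.condition_on(x_G)
        xm = null.m0(x_G)
        Gp = Gp - xm[:, None] * ((xm @ Gp) / float(xm @ xm))
    U = G.T @ r
    Q = float(U @ U)
    sg = np.sqrt(null.gamma_)
    lam = np.linalg.eigvalsh((Gp.T @ Gp) * np.outer(sg, sg))
    return wchi2_sf(Q, lam)


def cauchy_combine(p_env: np.ndarray, p_vc: float | None):
    """Aggregate the q single-environment p-values and the VC p-value.

    Each single-environment p-value receives weight ``1/(2q)`` and the
    variance-component p-value weight ``1/2``.  Unavailable (NaN)
    components are dropped and the remaining weights renormalized to sum
    to one, preserving the standard-Cauchy null.  Returns ``(T, p)``.
    """
    p_env = np.asarray(p_env, dtype=np.float64).ravel()
    if p_env.size == 0:
        raise InvalidInputError("p_env must contain at least one p-value")
    ok = np.isfinite(p_env)
    if not ok.any() and (p_vc is None or not np.isfinite(p_vc)):
        raise InvalidInputError("no finite p-values to combine")
    q_eff = int(ok.sum())
    w_env = np.zeros(p_env.shape)
    have_vc = p_vc is not None and np.isfinite(p_vc)
    if q_eff:
        w_env[ok] = 0.5 / q_eff if have_vc else 1.0 / q_eff
    w_vc = 0.5 if have_vc else 0.0
    if not q_eff:
        w_vc = 1.0
    pc = np.clip(p_env[ok], P_CLIP_LO, P_CLIP_HI)
    T = float(np.sum(w_env[ok] * np.tan((0.5 - pc) * np.pi)))
    if have_vc:
        T += w_vc * float(np.tan((0.5 - np.clip(p_vc, P_CLIP_LO,
                                                P_CLIP_HI)) * np.pi))
    return T, float(_cauchy_tail(T))


def minp_single_env_combine(p_env: np.ndarray) -> float:
    """Bonferroni-adjusted minimum over the single-environment p-values."""
    p_env = np.asarray(p_env, dtype=np.float64).ravel()
    if p_env.size == 0:
        raise InvalidInputError("p_env must contain at least one p-value")
    p = p_env[np.isfinite(p_env)]
    if p.size == 0:
        return 1.0
    return float(min(1.0, p.size * p.min()))


# ---------------------------------------------------------------------------
# genome-wide scan


def _qc_standardize_block(raw: np.ndarray, maf_min: float,
                          max_missing: float):
    """Mean-impute, QC and standardize a block of dosage columns.

    Returns ``(X_std, keep, maf, miss_rate)`` where ``keep`` marks columns
    passing the MAF/missingness filters (failing columns are zeroed in
    ``X_std`` so downstream algebra stays shaped).
    """
    X = np.array(raw, dtype=np.float64)
    n = X.shape[0]
    miss = np.isnan(X)
    miss_rate = miss.mean(axis=0)
    col_mean = np.nanmean(np.where(miss, np.nan, X), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    X = np.where(miss, col_mean[None, :], X)
    af = col_mean / 2.0
    maf = np.minimum(af, 1.0 - af)
    sd = X.std(axis=0, ddof=1)
    keep = (maf >= maf_min) & (miss_rate <= max_missing) & (sd > 0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    X = (X - X.mean(axis=0)) / sd_safe
    X[:, ~keep] = 0.0
    return X, keep, maf, miss_rate


def _scan_mixed_block(null: GxENullModel, Xb: np.ndarray, keep: np.ndarray,
                      X_E: np.ndarray, E2_flat: np.ndarray | None,
                      need_vc: bool):
    """All per-SNP mixed-model test pieces for one standardized block.

    Score numerators use the precomputed generalized residuals (which
    are exactly orthogonal to the fixed covariates, so projecting the
    predictors changes nothing there); denominators use the
    per-environment calibration factors applied to covariate-projected
    predictor norms.
    """
    n, B = Xb.shape
    q = X_E.shape[1]
    r = null.residuals_
    gamma = np.asarray(null.gamma_)          # (q,) per-environment
    gscale = np.sqrt(np.outer(gamma, gamma))
    Q0 = null._Q0                            # (n, c) orthonormal covariates
    c = Q0.shape[1]

    U_main = Xb.T @ r
    QtX = Q0.T @ Xb
    ss_main = np.einsum("ij,ij->j", Xb, Xb) - np.einsum("cj,cj->j", QtX, QtX)
    ss_safe = np.where(ss_main > 0, ss_main, 1.0)
    z_main = U_main / np.sqrt(null.gamma_main_ * ss_safe)
    beta_main = U_main / (null.gamma_main_ * ss_safe)
    p_main = _p_from_z(z_main)
    p_main[ss_main <= 0] = np.nan

    rXE = r[:, None] * X_E
    U_env = Xb.T @ rXE                       # (B, q)
    X2 = Xb * Xb
    den_env = X2.T @ (X_E * X_E)             # raw d'd per (SNP, env)
    # covariate projections of every interaction predictor
    A0 = np.empty((B, c, q))
    for ci in range(c):
        A0[:, ci, :] = (Xb * Q0[:, ci][:, None]).T @ X_E
    den_proj = den_env - np.einsum("jcq,jcq->jq", A0, A0)
    den_safe = np.where(den_proj > 1e-10, den_proj, 1.0)
    z_env = U_env / np.sqrt(gamma[None, :] * den_safe)
    p_env = _p_from_z(z_env)
    p_env[den_proj <= 1e-10] = 1.0

    p_vc = np.full(B, np.nan)
    S_proj = None
    if need_vc:
        S = (X2.T @ E2_flat).reshape(B, q, q)
        S_proj = (S - np.matmul(A0.transpose(0, 2, 1), A0)) / q
        lam = np.linalg.eigvalsh(S_proj * gscale[None, :, :])
        Q = np.einsum("jk,jk->j", U_env, U_env) / q
        p_vc = wchi2_sf_batch(Q, lam)

    # exact conditioning on the genotype for SNPs with a real main effect
    flagged = np.flatnonzero((p_main <= MAIN_EFFECT_FILTER_P) & keep)
    for j in flagged:
        x = Xb[:, j]
        r_x, _, _ = null.condition_on(x)
        xm = null.m0(x)
        xm2 = float(xm @ xm)
        D = x[:, None] * X_E                 # (n, q)
        w = xm @ D                           # projected-genotype overlap
        U_j = D.T @ r_x
        ss_j = den_proj[j] - w ** 2 / xm2
        ss_j = np.where(ss_j > 1e-10, ss_j, np.nan)
        z_j = U_j / np.sqrt(gamma * ss_j)
        p_env[j] = np.where(np.isfinite(z_j), _p_from_z(z_j), 1.0)
        if need_vc:
            S_j = S_proj[j] - np.outer(w, w) / (q * xm2)
            lam_j = np.linalg.eigvalsh(S_j * gscale)
            Q_j = float(U_j @ U_j) / q
            p_vc[j] = wchi2_sf(Q_j, np.maximum(lam_j, 0.0))
    beta_out = np.where(p_main <= MAIN_EFFECT_FILTER_P, beta_main, 0.0)
    return beta_out, p_main, p_env, p_vc


def _scan_fixed_block(Xb: np.ndarray, keep: np.ndarray, Q0: np.ndarray,
                      y_t: np.ndarray, X_E: np.ndarray,
                      E2_flat: np.ndarray):
    """Per-SNP fixed-effects variance-component test (no polygenic terms).

    Emulates the multi-environment strategy that ignores polygenic and
    polygenic-interaction random effects: OLS with environment (and user)
    fixed covariates plus the SNP main effect, then an exact
    weighted-chi-square score test of the q interaction terms.
    """
    n, B = Xb.shape
    q = X_E.shape[1]
    c = Q0.shape[1]
    Xt = Xb - Q0 @ (Q0.T @ Xb)               # covariate-projected genotypes
    ss_t = np.einsum("ij,ij->j", Xt, Xt)
    ss_safe = np.where(ss_t > 0, ss_t, 1.0)
    beta = (Xt.T @ y_t) / ss_safe
    yty = float(y_t @ y_t)
    rss = yty - beta ** 2 * ss_t
    dof = n - c - 1
    sigma2 = rss / dof
    tstat = beta * np.sqrt(ss_t) / np.sqrt(np.where(sigma2 > 0, sigma2, 1.0))
    p_main = _p_from_z(tstat)

    # score numerators U_jk = sum_i xg_ij (y_t - beta_j xt_j)_i xe_ik
    T1 = Xb.T @ (y_t[:, None] * X_E)
    T2 = np.einsum("ij,ij->j", Xb, Xt)       # here equals ss via projection
    Cross = (Xb * Xt).T @ X_E                # hmm replaced below if needed
    U = T1 - beta[:, None] * Cross

    X2 = Xb * Xb
    S = (X2.T @ E2_flat).reshape(B, q, q)    # D'D per SNP
    # covariate projection of D: subtract A_j' A_j with A_j = Q0' D_j
    A = np.empty((B, c, q))
    for ci in range(c):
        A[:, ci, :] = (Xb * Q0[:, ci][:, None]).T @ X_E
    S_t = S - np.matmul(A.transpose(0, 2, 1), A)
    # further project off the SNP's own (projected) genotype
    V1 = (Xt * Xb).T @ X_E                   # xt' d_k
    S_h = S_t - V1[:, :, None] * V1[:, None, :] / ss_safe[:, None, None]

    Q = np.einsum("jk,jk->j", U, U) / q
    lam = sigma2[:, None] * np.linalg.eigvalsh(S_h) / q
    lam = np.maximum(lam, 0.0)
    p_vc = wchi2_sf_batch(Q, lam)
    p_vc[~keep | (ss_t <= 0)] = np.nan
    return beta, p_main, p_vc


def genome_scan(design: StandardizedDesign, kernels: KernelSet | None,
                genotypes: np.ndarray, mode: str = "fastgxe",
                variants: pd.DataFrame | None = None,
                null: GxENullModel | None = None,
                block_size: int = 512, maf_min: float = 0.01,
                max_missing: float = 0.05, include_env_p: bool = False,
                random_state: int | None = None) -> pd.DataFrame:
    """Scan every SNP for GxE interaction and return one record per SNP.

    Parameters
    ----------
    genotypes : (n, m) raw allele dosages (0/1/2, NaN for missing) in the
        sample order of ``design``.
    mode : {"fastgxe", "minp", "vc_only_nopoly"}
        Test strategy (combined Cauchy test, Bonferroni minimum over
        single-environment tests, or fixed-effects variance-component
        test without polygenic control).
    variants : optional table with columns snp/chrom/pos/a1/a2, one row
        per genotype column.

    Returns a DataFrame with columns snp, chrom, pos, a1, a2, maf,
    beta_main, p_main, p_vc, T, p_gxe (plus p_env_1..q when
    ``include_env_p``).
    """
    if mode not in ("fastgxe", "minp", "vc_only_nopoly"):
        raise InvalidInputError(f"unknown scan mode {mode!r}")
    genotypes = np.asarray(genotypes)
    n, m = genotypes.shape
    if n != design.n:
        raise InvalidInputError(
            f"genotype rows ({n}) do not match design samples ({design.n})")
    X_E = design.X_E
    q = X_E.shape[1]
    E2_flat = (X_E[:, :, None] * X_E[:, None, :]).reshape(n, q * q)

    if mode == "vc_only_nopoly":
        W0 = np.column_stack([design.W, X_E])
        Q0, _ = np.linalg.qr(W0)
        y_t = design.y - Q0 @ (Q0.T @ design.y)
    else:
        if null is None:
            rng = np.random.default_rng(random_state)
            cols = rng.choice(m, size=min(500, m), replace=False)
            Xg, keep0, _, _ = _qc_standardize_block(
                genotypes[:, cols], maf_min, max_missing)
            null = GxENullModel(random_state=random_state).fit(
                design, kernels, gamma_genotypes=Xg[:, keep0])

    rows = []
    env_blocks = []
    for start in range(0, m, block_size):
        blk = slice(start, min(start + block_size, m))
        Xb, keep, maf, miss = _qc_standardize_block(
            genotypes[:, blk], maf_min, max_missing)
        B = Xb.shape[1]
        if mode == "vc_only_nopoly":
            beta, p_main, p_vc = _scan_fixed_block(
                Xb, keep, Q0, y_t, X_E, E2_flat)
            p_env = np.full((B, q), np.nan)
            T = np.full(B, np.nan)
            p_gxe = p_vc
        else:
            need_vc = mode == "fastgxe"
            beta, p_main, p_env, p_vc = _scan_mixed_block(
                null, Xb, keep, X_E, E2_flat, need_vc)
            if mode == "fastgxe":
                Tp = [cauchy_combine(p_env[j],
                                     p_vc[j] if np.isfinite(p_vc[j]) else None)
                      for j in range(B)]
                T = np.array([t for t, _ in Tp])
                p_gxe = np.array([p for _, p in Tp])
            else:
                T = np.full(B, np.nan)
                p_gxe = np.array([minp_single_env_combine(p_env[j])
                                  for j in range(B)])
        rec = pd.DataFrame({
            "maf": maf, "beta_main": beta, "p_main": p_main,
            "p_vc": p_vc, "T": T, "p_gxe": np.where(keep, p_gxe, np.nan),
            "qc_pass": keep,
        })
        rows.append(rec)
        if include_env_p:
            env_blocks.append(p_env)

    out = pd.concat(rows, ignore_index=True)
    if variants is not None:
        meta = variants.reset_index(drop=True)
        for col in ("snp", "chrom", "pos", "a1", "a2"):
            if col in meta.columns:
                out.insert(0, col, meta[col]) if col == "snp" else None
        out = pd.concat([meta[[c for c in ("snp", "chrom", "pos", "a1", "a2")
                               if c in meta.columns]],
                         out.drop(columns=[c for c in ("snp",)
                                           if c in out.columns])], axis=1)
    else:
        out.insert(0, "snp", [f"snp{i}" for i in range(m)])
    if include_env_p:
        env = np.vstack(env_blocks)
        for k in range(q):
            out[f"p_env_{k + 1}"] = env[:, k]
    return out
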