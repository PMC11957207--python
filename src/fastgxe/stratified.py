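"""Stratified validation of GxE signals via aggregated environment scores.

Each individual gets an aggregated interacting-environment (AIE) score
``X_E b_hat``, the linear combination of their environmental exposures
weighted by the posterior interaction effects from environment
selection.  Individuals are split into five near-equal AIE quintile
groups; within each group the SNP *main* effect is re-estimated with a
linear mixed model (polygenic random effect only, no interaction term).
A genuine interaction shows up as group-dependent main effects, tested
with the Wald statistic

    W = (R b)' [R var(b) R']^{-1} (R b)  ~  chi2(g - 1) under H0,

where R is the successive-difference contrast matrix (rows
``beta_i - beta_{i+1}``) and var(b) is diagonal because the groups are
disjoint samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from .kernels import InvalidInputError
from .varcomp import DegenerateModelError

GROUP_SIGNIFICANCE_P = 1e-8   # 5e-8 adjusted for five groups


@dataclass
class StratifiedResult:
    snp_id: str
    group_edges: np.ndarray
    n_per_group: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    p_group: np.ndarray
    W: float
    p_wald: float
    R: np.ndarray


def aie_scores(X_E: np.ndarray, b_gxe_post: np.ndarray) -> np.ndarray:
    """Aggregated interacting-environment score ``X_E b_hat`` per person."""
    X_E = np.asarray(X_E, dtype=np.float64)
    b = np.asarray(b_gxe_post, dtype=np.float64).ravel()
    if X_E.shape[1] != b.size:
        raise InvalidInputError("effect vector length does not match q")
    return X_E @ b


def quintile_groups(scores: np.ndarray, n_groups: int = 5) -> np.ndarray:
    """Rank-based split into near-equal groups (labels 1..n_groups).

    Ties are broken by stable input order, so fully tied scores fall back
    to a split by sample position.
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    n = scores.size
    if n < n_groups:
        raise InvalidInputError(f"need at least {n_groups} samples")
    if np.ptp(scores) == 0:
        warnings.warn("all scores tied; grouping by input order",
                      UserWarning, stacklevel=2)
    order = np.argsort(scores, kind="stable")
    labels = np.empty(n, dtype=np.int64)
    # first (n mod g) groups get the extra samples
    sizes = np.full(n_groups, n // n_groups)
    sizes[: n % n_groups] += 1
    start = 0
    for g, size in enumerate(sizes, start=1):
        labels[order[start:start + size]] = g
        start += size
    return labels


def successive_difference_contrast(g: int) -> np.ndarray:
    """(g-1) x g matrix with rows (..., 1, -1, ...)."""
    R = np.zeros((g - 1, g))
    idx = np.arange(g - 1)
    R[idx, idx] = 1.0
    R[idx, idx + 1] = -1.0
    return R


def per_group_effect(y: np.ndarray, x_G: np.ndarray,
                     K_G: np.ndarray | None = None,
                     W: np.ndarray | None = None,
                     min_size: int | None = None):
    """SNP main-effect estimate within one group.

    Fits ``y = W a + x_G b + u + e`` with ``u ~ N(0, K_G sigma_g2)`` by a
    small method-of-moments variance fit followed by GLS; with
    ``K_G=None`` (or sigma_g2 = 0) this reduces to OLS.  Returns
    ``(beta, se, p)``.
    """
    y = np.asarray(y, dtype=np.float64).ravel()
    x = np.asarray(x_G, dtype=np.float64).ravel()
    n = y.size
    if W is None:
        W = np.ones((n, 1))
    min_size = min_size if min_size is not None else W.shape[1] + 11
    if n < min_size:
        return np.nan, np.nan, np.nan
    X = np.column_stack([W, x])

    if K_G is not None:
        # two-component moment fit: sigma_g2 K + sigma_e2 I
        Q, _ = np.linalg.qr(X)
        y_p = y - Q @ (Q.T @ y)
        KQ = K_G @ Q
        A = K_G - KQ @ Q.T - Q @ KQ.T + Q @ ((Q.T @ KQ) @ Q.T)
        c = Q.shape[1]
        tA = float(np.trace(A))
        M = np.array([[float(np.sum(A * A)), tA],
                      [tA, float(n - c)]])
        b_vec = np.array([y_p @ (A @ y_p), y_p @ y_p])
        try:
            sg2, se2 = np.linalg.solve(M, b_vec)
        except np.linalg.LinAlgError as exc:
            raise DegenerateModelError("singular group moment system") from exc
        sg2 = max(sg2, 0.0)
        if sg2 == 0.0:
            se2 = float(b_vec[1] / (n - c))
        V = sg2 * K_G + max(se2, 1e-12) * np.eye(n)
        chol = cho_factor(V, lower=True, check_finite=False)
        ViX = cho_solve(chol, X, check_finite=False)
        XtViX = X.T @ ViX
        cov = np.linalg.inv(XtViX)
        coef = cov @ (ViX.T @ y)
    else:
        XtX = X.T @ X
        cov_u = np.linalg.inv(XtX)
        coef = cov_u @ (X.T @ y)
        resid = y - X @ coef
        s2 = float(resid @ resid) / (n - X.shape[1])
        cov = cov_u * s2
    beta = float(coef[-1])
    se = float(np.sqrt(cov[-1, -1]))
    z = beta / se
    p = float(chi2.sf(z * z, 1))
    return beta, se, p


def wald_heterogeneity(beta: np.ndarray, var: np.ndarray):
    """Wald test of equal group effects; returns ``(W, p)``.

    ``var`` may be a vector of squared standard errors or a full
    covariance matrix; the null distribution is chi2 with
    (number of groups - 1) degrees of freedom.
    """
    beta = np.asarray(beta, dtype=np.float64).ravel()
    g = beta.size
    var = np.asarray(var, dtype=np.float64)
    V = np.diag(var) if var.ndim == 1 else var
    if np.any(np.diag(V) <= 0) or not np.all(np.isfinite(V)):
        raise InvalidInputError("group variances must be positive finite")
    R = successive_difference_contrast(g)
    Rb = R @ beta
    M = R @ V @ R.T
    try:
        sol = np.linalg.solve(M, Rb)
    except np.linalg.LinAlgError as exc:
        raise InvalidInputError("singular contrast covariance") from exc
    W = float(Rb @ sol)
    return W, float(chi2.sf(W, g - 1))


def stratified_analysis(design, x_G: np.ndarray, b_gxe_post: np.ndarray,
                        K_G: np.ndarray | None = None,
                        n_groups: int = 5,
                        snp_id: str = "") -> StratifiedResult:
    """Full AIE-score stratified validation for one SNP."""
    scores = aie_scores(design.X_E, b_gxe_post)
    labels = quintile_groups(scores, n_groups)
    edges = np.quantile(scores, np.linspace(0, 1, n_groups + 1))
    beta = np.empty(n_groups)
    se = np.empty(n_groups)
    p = np.empty(n_groups)
    sizes = np.empty(n_groups, dtype=int)
    for g in range(1, n_groups + 1):
        idx = labels == g
        sizes[g - 1] = idx.sum()
        Kg = K_G[np.ix_(idx, idx)] if K_G is not None else None
        beta[g - 1], se[g - 1], p[g - 1] = per_group_effect(
            design.y[idx], x_G[idx], K_G=Kg, W=design.W[idx])
    W_stat, p_wald = wald_heterogeneity(beta, se ** 2)
    return StratifiedResult(
        snp_id=snp_id, group_edges=edges, n_per_group=sizes,
        beta=beta, se=se, p_group=p, W=W_stat, p_wald=p_wald,
        R=successive_difference_contrast(n_groups))
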