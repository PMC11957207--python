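"""Method-of-moments variance components and interaction heritability.

The phenotype covariance is modeled as

    V = sigma_g^2 K_G + sigma_v^2 K_GxE + sigma_e^2 I,

and the three components are estimated by matching observed quadratic
forms to their expectations (an MQS-type estimator).  With fixed
covariates W projected out (projector P0 = I - W W^+), the moment system
is

    [ tr(A_G A_G)   tr(A_G A_X)   tr(A_G) ] [sigma_g^2]   [y' A_G y]
    [ tr(A_X A_G)   tr(A_X A_X)   tr(A_X) ] [sigma_v^2] = [y' A_X y]
    [ tr(A_G)       tr(A_X)       n - c   ] [sigma_e^2]   [y' y    ]

with A = P0 K P0 and y already projected.  Traces of matrix products are
computed exactly for dense kernels (tr(AB) = sum(A * B)) or by the
Hutchinson randomized estimator ``tr(K1 K2) = E[w' K1 K2 w]`` with
standard-normal probe vectors (default s = 30 probes).

GxE heritability is the interaction share of phenotypic variance,
``h2_gxe = sigma_v^2 / (sigma_g^2 + sigma_v^2 + sigma_e^2)``.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse as sp
from sklearn.base import BaseEstimator

from .kernels import InvalidInputError


class DegenerateModelError(ValueError):
    """The moment system is singular (e.g. collinear kernels)."""


def hutchinson_trace(K1: np.ndarray, K2: np.ndarray, s: int,
                     seed: int | np.random.Generator | None = None,
                     probe: str = "normal") -> float:
    """Randomized estimate of ``tr(K1 K2)``.

    Averages ``w' K1 (K2 w)`` over ``s`` probe vectors ``w`` with i.i.d.
    standard-normal entries (or +-1 Rademacher entries when
    ``probe='rademacher'``, which has lower variance for some spectra).
    The estimator is unbiased for symmetric K1, K2.
    """
    if s < 1:
        raise InvalidInputError("number of probes s must be >= 1")
    if K1.shape != K2.shape:
        raise InvalidInputError("kernel dimensions differ")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    n = K1.shape[0]
    if probe == "normal":
        Wp = rng.standard_normal((n, s))
    elif probe == "rademacher":
        Wp = rng.choice([-1.0, 1.0], size=(n, s))
    else:
        raise InvalidInputError(f"unknown probe type {probe!r}")
    K2W = K2 @ Wp
    K1tW = K1 @ Wp  # K1 symmetric: w'K1 = (K1 w)'
    return float(np.sum(K1tW * K2W) / s)


def _project_out(W: np.ndarray | None, y: np.ndarray,
                 kernels: list[np.ndarray]):
    """Residualize y and kernels on covariates W (thin QR projector)."""
    if W is None:
        return y, kernels, 0
    Q, _ = np.linalg.qr(W)
    c = Q.shape[1]
    y = y - Q @ (Q.T @ y)
    proj = []
    for K in kernels:
        KQ = K @ Q
        A = K - KQ @ Q.T - Q @ KQ.T + Q @ ((Q.T @ KQ) @ Q.T)
        proj.append(0.5 * (A + A.T))
    return y, proj, c


class MoMVarianceComponents(BaseEstimator):
    """Method-of-moments estimator of (sigma_g^2, sigma_v^2, sigma_e^2).

    Parameters
    ----------
    s : int
        Number of Hutchinson probe vectors when traces are estimated.
    exact_traces : bool or "auto"
        Compute product traces exactly (O(n^2) for dense kernels).  The
        default "auto" uses exact traces whenever dense kernels are given.
    probe : {"normal", "rademacher"}
        Probe distribution for the randomized trace estimator.
    random_state : int or None
        Seed for the probe vectors.

    Attributes
    ----------
    sigma_g2_, sigma_v2_, sigma_e2_ : float
        Non-negative component estimates (negative solutions are clipped
        to zero and the reduced system re-solved).
    h2_snp_, h2_gxe_ : float
        Polygenic and interaction shares of phenotypic variance.
    truncated_ : tuple of str
        Names of components clipped at zero.
    """

    def __init__(self, s: int = 30, exact_traces: bool | str = "auto",
                 probe: str = "normal", random_state: int | None = None):
        self.s = s
        self.exact_traces = exact_traces
        self.probe = probe
        self.random_state = random_state

    def fit(self, y: np.ndarray, K_G: np.ndarray, K_GxE: np.ndarray,
            W: np.ndarray | None = None):
        y = np.asarray(y, dtype=np.float64).ravel()
        if not np.all(np.isfinite(y)):
            raise InvalidInputError("non-finite phenotype values")
        if sp.issparse(K_G):
            K_G = np.asarray(K_G.todense())
        n = y.shape[0]
        if K_G.shape != (n, n) or K_GxE.shape != (n, n):
            raise InvalidInputError("kernels not conformable with y")
        if self.s < 1:
            raise InvalidInputError("s must be >= 1")

        y_p, (A_G, A_X), c = _project_out(W, y, [K_G, K_GxE])

        use_exact = (self.exact_traces is True or
                     (self.exact_traces == "auto"))
        rng = np.random.default_rng(self.random_state)
        tr_G = float(np.trace(A_G))
        tr_X = float(np.trace(A_X))
        if use_exact:
            t_GG = float(np.sum(A_G * A_G))
            t_GX = float(np.sum(A_G * A_X))
            t_XX = float(np.sum(A_X * A_X))
        else:
            t_GG = hutchinson_trace(A_G, A_G, self.s, rng, self.probe)
            t_GX = hutchinson_trace(A_G, A_X, self.s, rng, self.probe)
            t_XX = hutchinson_trace(A_X, A_X, self.s, rng, self.probe)

        A = np.array([[t_GG, t_GX, tr_G],
                      [t_GX, t_XX, tr_X],
                      [tr_G, tr_X, float(n - c)]])
        b = np.array([y_p @ (A_G @ y_p), y_p @ (A_X @ y_p), y_p @ y_p])

        if np.linalg.cond(A) > 1e10:
            raise DegenerateModelError(
                "moment system is numerically singular; "
                "kernels are (near-)collinear")

        names = ["sigma_g2", "sigma_v2", "sigma_e2"]
        active = [0, 1, 2]
        sol = np.linalg.solve(A, b)
        truncated: list[str] = []
        while np.any(sol < 0) and len(active) > 1:
            drop = active[int(np.argmin(sol))]
            truncated.append(names[drop])
            active = [i for i in active if i != drop]
            sub = np.ix_(active, active)
            sol = np.linalg.solve(A[sub], b[active])
        full = np.zeros(3)
        for i, a in enumerate(active):
            full[a] = max(sol[i], 0.0)

        self.sigma_g2_, self.sigma_v2_, self.sigma_e2_ = full
        total = full.sum()
        if total <= 0:
            raise DegenerateModelError("all variance components are zero")
        self.h2_snp_ = self.sigma_g2_ / total
        self.h2_gxe_ = self.sigma_v2_ / total
        self.truncated_ = tuple(truncated)
        self.n_trace_probes_ = self.s if not use_exact else 0
        self.system_ = (A, b)
        self.n_samples_ = n
        return self


def mom_fit(y: np.ndarray, K_G: np.ndarray, K_GxE: np.ndarray,
            W: np.ndarray | None = None, s: int = 30,
            seed: int | None = None,
            exact_traces: bool | str = "auto") -> MoMVarianceComponents:
    """Functional wrapper around :class:`MoMVarianceComponents`."""
    return MoMVarianceComponents(
        s=s, exact_traces=exact_traces, random_state=seed,
    ).fit(y, K_G, K_GxE, W=W)


def gxe_heritability(vc) -> float:
    """Interaction heritability sigma_v^2 / (sigma_g^2+sigma_v^2+sigma_e^2).

    Accepts a fitted :class:`MoMVarianceComponents` or a 3-sequence of
    non-negative components.
    """
    if hasattr(vc, "sigma_v2_"):
        comps = np.array([vc.sigma_g2_, vc.sigma_v2_, vc.sigma_e2_])
    else:
        comps = np.asarray(vc, dtype=np.float64)
    if np.any(comps < 0):
        raise InvalidInputError("variance components must be non-negative")
    total = comps.sum()
    if total <= 0:
        raise InvalidInputError("all variance components are zero")
    return float(comps[1] / total)
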