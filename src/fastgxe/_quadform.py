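"""Tail probabilities of positive weighted sums of chi-square(1) variables.

The variance-component score statistic has null distribution
``Q ~ sum_k lambda_k chi2_1``.  Its survival function is computed by
numerical inversion of the characteristic function (the Davies/Imhof
integral), with the Kuonen saddlepoint approximation for deep tails and
Liu moment matching as a last-resort fallback.  The inversion is
vectorized across many (statistic, weights) pairs so a genome-wide scan
can evaluate thousands of such tests per second.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special
from scipy.stats import chi2, ncx2, norm

_EPS_WEIGHT = 1e-12  # relative cutoff below which weights are dropped


def _clean_weights(lam: np.ndarray) -> np.ndarray:
    lam = np.asarray(lam, dtype=np.float64).ravel()
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("no positive weights")
    return lam[lam > lam.max() * _EPS_WEIGHT]


def liu_sf(x: float, lam: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matching approximation to P(Q > x)."""
    lam = _clean_weights(lam)
    c1, c2, c3, c4 = (np.sum(lam ** k) for k in (1, 2, 3, 4))
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2 * delta
    else:
        a = 1.0 / s1
        delta = 0.0
        df = c2 ** 3 / c3 ** 2
    mu_q, sigma_q = c1, np.sqrt(2 * c2)
    mu_x, sigma_x = df + delta, np.sqrt(2) * a
    t = (x - mu_q) / sigma_q * sigma_x + mu_x
    if delta > 0:
        return float(ncx2.sf(t, df, delta))
    return float(chi2.sf(t, df))


def saddlepoint_sf(x: float, lam: np.ndarray) -> float:
    """Kuonen saddlepoint (Lugannani-Rice) approximation to P(Q > x)."""
    lam = _clean_weights(lam)
    mean = lam.sum()
    if abs(x - mean) < 1e-8 * max(mean, 1.0):
        return 0.5
    lmax = lam.max()
    upper = 1.0 / (2 * lmax)

    def kprime(z):
        return np.sum(lam / (1 - 2 * z * lam))

    # bracket the saddlepoint zeta with K'(zeta) = x
    if x > mean:
        lo, hi = 0.0, upper * (1 - 1e-12)
        while kprime(hi) < x:
            hi = upper - (upper - hi) * 0.1
            if upper - hi < 1e-300:
                return 0.0
    else:
        lo = -1.0
        while kprime(lo) > x:
            lo *= 2.0
            if lo < -1e12:
                return 1.0
        hi = 0.0
    zeta = optimize.brentq(lambda z: kprime(z) - x, lo, hi, xtol=1e-14)
    if zeta == 0.0:
        return 0.5
    K = -0.5 * np.sum(np.log1p(-2 * zeta * lam))
    Kpp = 2 * np.sum(lam ** 2 / (1 - 2 * zeta * lam) ** 2)
    w = np.sign(zeta) * np.sqrt(2 * (zeta * x - K))
    v = zeta * np.sqrt(Kpp)
    if abs(w) < 1e-8:
        return 0.5
    z = w + np.log(v / w) / w
    return float(norm.sf(z))


def _imhof_nodes(lam: np.ndarray, x: float, tol: float) -> tuple[np.ndarray, np.ndarray]:
    """Integration nodes/weights for one Imhof integral on (0, U]."""
    k = lam.size / 2.0
    log_c = 0.5 * np.sum(np.log(lam))
    # Imhof's truncation bound: tail beyond U is below tol
    logU = -(np.log(np.pi) + np.log(k) + np.log(tol) + log_c) / k
    U = np.exp(min(logU, 700.0 / max(k, 1.0)))
    U = min(max(U, 1e-8), 1e8)
    # resolve the sin(theta) oscillation, frequency ~ x/2 rad per unit u
    n_osc = U * (abs(x) + lam.sum()) / (4 * np.pi)
    n_nodes = int(min(max(128, 16 * n_osc), 1 << 14))
    nodes, weights = np.polynomial.legendre.leggauss(min(n_nodes, 512))
    if n_nodes <= 512:
        u = 0.5 * U * (nodes + 1)
        w = 0.5 * U * weights
        return u, w
    # panelized Gauss rule for highly oscillatory cases
    n_panel = int(np.ceil(n_nodes / 512))
    edges = np.linspace(0.0, U, n_panel + 1)
    us, ws = [], []
    for a, b in zip(edges[:-1], edges[1:]):
        us.append(0.5 * (b - a) * (nodes + 1) + a)
        ws.append(0.5 * (b - a) * weights)
    return np.concatenate(us), np.concatenate(ws)


def imhof_sf(x: float, lam: np.ndarray, tol: float = 1e-12) -> float:
    """P(Q > x) by numerical characteristic-function inversion."""
    lam = _clean_weights(lam)
    u, w = _imhof_nodes(lam, x, tol)
    lu = lam[None, :] * u[:, None]
    theta = 0.5 * np.sum(np.arctan(lu), axis=1) - 0.5 * x * u
    log_rho = 0.25 * np.sum(np.log1p(lu ** 2), axis=1)
    integrand = np.sin(theta) * np.exp(-log_rho) / u
    p = 0.5 + (w @ integrand) / np.pi
    return float(p)


def wchi2_sf(x: float, lam: np.ndarray, tol: float = 1e-12) -> float:
    """Survival function of ``sum lambda_k chi2_1`` at ``x``.

    Uses the inversion integral in the body of the distribution and the
    saddlepoint approximation in the tails, with Liu moment matching if
    both fail.  The result is clipped to (0, 1].
    """
    lam = _clean_weights(lam)
    if x <= 0:
        return 1.0
    if np.ptp(lam) <= 1e-12 * lam.max():
        # equal weights: exactly a scaled chi-square
        return float(min(max(chi2.sf(x / lam.mean(), lam.size), 5e-324), 1.0))
    if lam.size <= 4:
        # too few weights for the blocked inversion (the integrand decays
        # like u^{-(q/2+1)}); the saddlepoint is accurate here
        p = saddlepoint_sf(x, lam)
        if not np.isfinite(p) or p <= 0.0:
            p = liu_sf(x, lam)
        return float(min(max(p, 5e-324), 1.0))
    p_liu = liu_sf(x, lam)
    if p_liu < 1e-7 or p_liu > 1 - 1e-7:
        p = saddlepoint_sf(x, lam)
        if not np.isfinite(p) or p <= 0.0:
            p = p_liu
        return float(min(max(p, 5e-324), 1.0))
    p = imhof_sf(x, lam, tol)
    if not (tol * 0.5 < p <= 1.0 + 1e-9):
        p = saddlepoint_sf(x, lam)
        if not np.isfinite(p) or p <= 0.0:
            p = p_liu
    return float(min(max(p, 5e-324), 1.0))


def wchi2_sf_batch(xs: np.ndarray, lams: np.ndarray,
                   tol: float = 1e-7) -> np.ndarray:
    """Vectorized survival function for many tests sharing weight count.

    ``xs``: (n_tests,) statistics; ``lams``: (n_tests, q) weight rows.
    A shared integration strategy handles the central cases in one blocked
    pass; tail cases are routed to the saddlepoint individually.
    """
    xs = np.asarray(xs, dtype=np.float64)
    lams = np.asarray(lams, dtype=np.float64)
    n = xs.shape[0]
    out = np.empty(n)
    lam_pos = np.where(lams > 0, lams, 0.0)
    lam_max = lam_pos.max(axis=1)
    lam_pos = np.where(lam_pos > lam_max[:, None] * _EPS_WEIGHT, lam_pos, 0.0)
    c1 = lam_pos.sum(axis=1)
    c2 = (lam_pos ** 2).sum(axis=1)
    # route far tails (cheap z-score screen) and few-weight cases to the
    # scalar path
    zish = (xs - c1) / np.sqrt(2 * c2)
    n_pos = (lam_pos > 0).sum(axis=1)
    tail = (zish > 5.5) | (xs <= 0) | (n_pos <= 4)
    for i in np.flatnonzero(tail):
        out[i] = 1.0 if xs[i] <= 0 else wchi2_sf(xs[i], lam_pos[i], tol=1e-12)
    central = np.flatnonzero(~tail)
    if central.size == 0:
        return out
    # blocked Imhof integration with a per-case upper limit
    lam_c = lam_pos[central]
    x_c = xs[central]
    with np.errstate(divide="ignore"):
        logl = np.where(lam_c > 0, np.log(np.where(lam_c > 0, lam_c, 1.0)), 0.0)
    k = (lam_c > 0).sum(axis=1) / 2.0
    log_c = 0.5 * logl.sum(axis=1)
    logU = -(np.log(np.pi) + np.log(k) + np.log(tol) + log_c) / k
    U = np.exp(np.minimum(logU, 700.0 / np.maximum(k, 1.0)))
    U = np.clip(U, 1e-8, 1e8)
    n_osc = U * (np.abs(x_c) + c1[central]) / (4 * np.pi)
    n_nodes = np.clip((6 * n_osc).astype(int), 64, 1 << 13)
    # bucket cases by node count so each bucket is one dense evaluation
    buckets = np.ceil(np.log2(n_nodes / 64)).astype(int).clip(0, None)
    base_nodes, base_w = np.polynomial.legendre.leggauss(64)
    for b in np.unique(buckets):
        idx = central[buckets == b]
        sel = buckets == b
        n_panel = 1 << b
        Ub = U[sel]
        lam_b = lam_pos[idx]
        x_b = xs[idx]
        edges = np.linspace(0.0, 1.0, n_panel + 1)
        us, ws = [], []
        for a, bb in zip(edges[:-1], edges[1:]):
            us.append(0.5 * (bb - a) * (base_nodes + 1) + a)
            ws.append(np.full_like(base_w, 0.5 * (bb - a)) * base_w)
        u01 = np.concatenate(us)          # nodes on (0,1)
        w01 = np.concatenate(ws)
        # chunk over cases so the (cases, nodes, q) tensor stays small
        chunk = max(1, int(4e6 / (u01.size * lam_b.shape[1] or 1)))
        for s in range(0, len(idx), chunk):
            sl = slice(s, s + chunk)
            u = Ub[sl, None] * u01[None, :]      # (chunk, nodes)
            w = Ub[sl, None] * w01[None, :]
            lu = lam_b[sl, None, :] * u[:, :, None]
            theta = 0.5 * np.arctan(lu).sum(axis=2) - 0.5 * x_b[sl, None] * u
            log_rho = 0.25 * np.log1p(lu ** 2).sum(axis=2)
            integrand = np.sin(theta) * np.exp(-log_rho) / u
            out[idx[sl]] = 0.5 + np.sum(w * integrand, axis=1) / np.pi
    # repair any numerically out-of-range central results
    bad = np.flatnonzero((out <= tol) | (out > 1.0 + 1e-9) | ~np.isfinite(out))
    for i in bad:
        out[i] = wchi2_sf(xs[i], lam_pos[i], tol=1e-12)
    return np.clip(out, 5e-324, 1.0)
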