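"""Table readers, sample alignment, and phenotype preprocessing.

Phenotypes, environments and covariates arrive as delimited text keyed
by sample ID; genotypes as PLINK bed/bim/fam.  Samples are aligned by
intersecting IDs in fam-file order, complete cases only.  Quantitative
traits are adjusted for covariates by linear regression and the
residuals mapped to normal scores with the rank-based inverse-normal
transform ``Phi^{-1}((rank - 0.5) / n)`` (ties receive averaged ranks).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .kernels import InvalidInputError, StandardizedDesign, standardize

logger = logging.getLogger("fastgxe")


@dataclass
class PhenotypeTable:
    sample_id: np.ndarray
    raw: np.ndarray
    adjusted: np.ndarray
    transform: str


def read_id_table(path: str | Path, id_col: str | int = 0) -> pd.DataFrame:
    """Read a delimited table and index it by sample ID.

    Tab/whitespace separated, '.' treated as missing; gzip inferred from
    the .gz suffix.
    """
    df = pd.read_csv(path, sep=None, engine="python", na_values=["."])
    if isinstance(id_col, int):
        id_col = df.columns[id_col]
    df[id_col] = df[id_col].astype(str)
    return df.set_index(id_col)


def adjust_and_transform(y_raw: np.ndarray,
                         covariates: np.ndarray | None = None
                         ) -> PhenotypeTable:
    """Covariate-adjust then inverse-normal transform a trait.

    OLS residuals on the covariates (an intercept is always included)
    are converted to normal scores ``Phi^{-1}((rank - 0.5)/n)``; tied
    values share the average rank and hence equal scores.
    """
    y = np.asarray(y_raw, dtype=np.float64).ravel()
    n = y.size
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=np.float64))
        if C.shape[0] != n:
            C = C.T
        X = np.column_stack([X, C])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns via QR pivoting on the diagonal of R
        _, R = np.linalg.qr(X)
        aliased = np.flatnonzero(np.abs(np.diag(R)) < 1e-10)
        raise InvalidInputError(
            f"rank-deficient covariates; aliased columns {aliased.tolist()}")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    scores = norm.ppf((rankdata(resid, method="average") - 0.5) / n)
    return PhenotypeTable(sample_id=np.arange(n), raw=y, adjusted=scores,
                          transform="ols-residual + rank inverse-normal "
                                    "(offset 0.5)")


def align_samples(fam: pd.DataFrame, pheno: pd.DataFrame,
                  env: pd.DataFrame, covar: pd.DataFrame | None = None,
                  transform_phenotype: bool = True) -> tuple[
                      StandardizedDesign, np.ndarray]:
    """Intersect sample IDs and build a standardized design.

    Order follows the fam file.  Samples missing any phenotype,
    environment, or covariate value are dropped (complete-case filter).
    Returns the design and the integer positions of the retained samples
    within the fam file (for subsetting genotypes).
    """
    ids = fam["iid"].astype(str).to_numpy()
    tables = [pheno, env] + ([covar] if covar is not None else [])
    common = set(ids)
    for t in tables:
        common &= set(t.index.astype(str))
    if not common:
        raise InvalidInputError("no overlapping sample IDs")
    keep_pos = np.array([i for i, s in enumerate(ids) if s in common])
    sel = ids[keep_pos]

    y = pheno.loc[sel].iloc[:, 0].to_numpy(dtype=np.float64)
    E = env.loc[sel].to_numpy(dtype=np.float64)
    C = covar.loc[sel].to_numpy(dtype=np.float64) if covar is not None \
        else None
    complete = np.isfinite(y) & np.all(np.isfinite(E), axis=1)
    if C is not None:
        complete &= np.all(np.isfinite(C), axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("dropped %d incomplete sample(s)", dropped)
    keep_pos = keep_pos[complete]
    sel = sel[complete]
    y, E = y[complete], E[complete]
    C = C[complete] if C is not None else None

    if transform_phenotype:
        y = adjust_and_transform(y, C).adjusted
    W = np.ones((len(sel), 1))
    if C is not None:
        W = np.column_stack([W, standardize(C)])
    design = StandardizedDesign(
        sample_ids=sel, y=standardize(y), X_G=None,
        X_E=standardize(E), W=W)
    logger.info("aligned %d samples", len(sel))
    return design, keep_pos
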