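"""Relationship kernels for the two-variance-component GxE mixed model.

The model decomposes phenotypic covariance into three structured parts:

* ``K_G``   — genomic relationship matrix (GRM), ``X_G X_G' / m`` over
  column-standardized genotype dosages, capturing polygenic covariance;
* ``K_E``   — environmental similarity, ``X_E X_E' / q`` over standardized
  environmental factors;
* ``K_GxE`` — Hadamard (elementwise) product ``K_G * K_E``, the covariance
  of polygenic genotype-environment interaction effects (PSD by the Schur
  product theorem).

Genotype columns are standardized with the sample SD (``ddof=1``) so the
GRM diagonal averages approximately one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import sparse as sp


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass
class StandardizedDesign:
    """Aligned, column-standardized phenotype/genotype/environment design.

    All columns of ``y``, ``X_G`` and ``X_E`` have mean 0 and SD 1 (sample
    SD).  ``W`` holds fixed covariates and always includes an intercept as
    its first column.
    """

    sample_ids: np.ndarray
    y: np.ndarray
    X_G: np.ndarray | None
    X_E: np.ndarray
    W: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        for name in ("y", "X_E", "W"):
            arr = getattr(self, name)
            if arr.shape[0] != n:
                raise InvalidInputError(
                    f"{name} has {arr.shape[0]} rows, expected {n}"
                )
        if self.X_G is not None and self.X_G.shape[0] != n:
            raise InvalidInputError("X_G row count does not match sample_ids")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def q(self) -> int:
        return self.X_E.shape[1]


@dataclass
class KernelSet:
    """The three symmetric PSD relationship matrices used by the model."""

    K_G: np.ndarray | sp.spmatrix
    K_E: np.ndarray
    K_GxE: np.ndarray
    m_snps: int
    sparse_threshold: float | None = None
    sample_ids: np.ndarray | None = field(default=None)

    def dense_grm(self) -> np.ndarray:
        if sp.issparse(self.K_G):
            return np.asarray(self.K_G.todense())
        return self.K_G


def standardize(raw_matrix: np.ndarray, min_variance: float = 1e-12,
                return_dropped: bool = False):
    """Center and scale each column to mean 0, sample SD 1.

    Columns whose variance does not exceed ``min_variance`` carry no
    information and are dropped with a warning.  An all-constant input is
    an error.

    Returns the standardized matrix, or ``(matrix, dropped_indices)`` when
    ``return_dropped`` is set.
    """
    X = np.asarray(raw_matrix, dtype=np.float64)
    one_dim = X.ndim == 1
    if one_dim:
        X = X[:, None]
    if not np.all(np.isfinite(X)):
        raise InvalidInputError("non-finite values in input matrix")
    var = X.var(axis=0, ddof=1)
    keep = var > min_variance
    dropped = np.flatnonzero(~keep)
    if dropped.size == X.shape[1]:
        raise InvalidInputError(
            f"all columns are (near-)constant: {dropped.tolist()}"
        )
    if dropped.size:
        warnings.warn(
            f"dropping {dropped.size} (near-)constant column(s): "
            f"{dropped.tolist()}", UserWarning, stacklevel=2,
        )
    X = X[:, keep]
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    if one_dim and X.shape[1] == 1:
        X = X[:, 0]
    if return_dropped:
        return X, dropped
    return X


def compute_grm(X_G: np.ndarray) -> np.ndarray:
    """GRM ``X_G X_G' / m`` from an n x m standardized genotype matrix."""
    X_G = np.asarray(X_G, dtype=np.float64)
    if X_G.ndim == 1:
        X_G = X_G[:, None]
    m = X_G.shape[1]
    if m == 0:
        raise InvalidInputError("GRM requires at least one SNP (m=0)")
    K = X_G @ X_G.T
    K /= m
    # force exact symmetry against accumulated rounding
    K += K.T
    K *= 0.5
    return K


def sparsify_grm(K_G: np.ndarray, threshold: float) -> sp.csr_matrix:
    """Zero small off-diagonal GRM entries; keep the diagonal intact.

    Entries with ``|K_ij| < threshold`` (i != j) are dropped and the result
    is stored sparse.  ``threshold=0`` is the identity operation.
    """
    if not 0.0 <= threshold < 1.0:
        raise InvalidInputError("threshold must be in [0, 1)")
    K = np.asarray(K_G, dtype=np.float64)
    off = np.where(np.abs(K) >= threshold, K, 0.0)
    np.fill_diagonal(off, np.diag(K))
    return sp.csr_matrix(off)


def compute_env_kernel(X_E: np.ndarray) -> np.ndarray:
    """Environmental similarity kernel ``X_E X_E' / q``."""
    X_E = np.asarray(X_E, dtype=np.float64)
    if X_E.ndim == 1:
        X_E = X_E[:, None]
    q = X_E.shape[1]
    if q == 0:
        raise InvalidInputError("environment kernel requires q >= 1")
    K = X_E @ X_E.T
    K /= q
    K += K.T
    K *= 0.5
    return K


def compute_gxe_kernel(K_G: np.ndarray | sp.spmatrix,
                       K_E: np.ndarray) -> np.ndarray:
    """Hadamard product kernel ``K_G * K_E`` (elementwise)."""
    if sp.issparse(K_G):
        K_G = np.asarray(K_G.todense())
    K_G = np.asarray(K_G, dtype=np.float64)
    K_E = np.asarray(K_E, dtype=np.float64)
    if K_G.shape != K_E.shape:
        raise InvalidInputError(
            f"kernel shapes differ: {K_G.shape} vs {K_E.shape}"
        )
    return K_G * K_E


def build_kernels(X_G: np.ndarray, X_E: np.ndarray,
                  sparse_threshold: float | None = None,
                  sample_ids: np.ndarray | None = None) -> KernelSet:
    """Construct the full :class:`KernelSet` from standardized matrices."""
    K_G = compute_grm(X_G)
    K_E = compute_env_kernel(X_E)
    K_GxE = compute_gxe_kernel(K_G, K_E)
    K_G_out: np.ndarray | sp.spmatrix = K_G
    if sparse_threshold is not None:
        K_G_out = sparsify_grm(K_G, sparse_threshold)
    return KernelSet(K_G=K_G_out, K_E=K_E, K_GxE=K_GxE,
                     m_snps=np.atleast_2d(X_G).shape[1],
                     sparse_threshold=sparse_threshold,
                     sample_ids=sample_ids)


def save_kernel_cache(kernels: KernelSet, prefix: str | Path) -> None:
    """Write a kernel cache: ids file, matrices, and a JSON sidecar."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    meta = {"m_snps": int(kernels.m_snps),
            "sparse_threshold": kernels.sparse_threshold,
            "n": int(kernels.K_E.shape[0])}
    if sp.issparse(kernels.K_G):
        sp.save_npz(str(prefix) + ".grm.npz", kernels.K_G.tocoo())
        meta["grm_format"] = "coo"
    else:
        np.save(str(prefix) + ".grm.npy", kernels.K_G)
        meta["grm_format"] = "dense"
    np.save(str(prefix) + ".env.npy", kernels.K_E)
    np.save(str(prefix) + ".gxe.npy", kernels.K_GxE)
    if kernels.sample_ids is not None:
        np.savetxt(str(prefix) + ".ids.txt",
                   np.asarray(kernels.sample_ids, dtype=str), fmt="%s")
    with open(str(prefix) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)


def load_kernel_cache(prefix: str | Path) -> KernelSet:
    prefix = str(prefix)
    with open(prefix + ".json") as fh:
        meta = json.load(fh)
    if meta["grm_format"] == "coo":
        K_G: np.ndarray | sp.spmatrix = sp.load_npz(prefix + ".grm.npz").tocsr()
    else:
        K_G = np.load(prefix + ".grm.npy")
    K_E = np.load(prefix + ".env.npy")
    K_GxE = np.load(prefix + ".gxe.npy")
    ids_path = Path(prefix + ".ids.txt")
    ids = np.loadtxt(ids_path, dtype=str) if ids_path.exists() else None
    return KernelSet(K_G=K_G, K_E=K_E, K_GxE=K_GxE,
                     m_snps=meta["m_snps"],
                     sparse_threshold=meta["sparse_threshold"],
                     sample_ids=ids)
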