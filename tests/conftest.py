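"""Shared fixtures: small simulated cohorts and kernels."""

from __future__ import annotations

import numpy as np
import pytest

from fastgxe.kernels import StandardizedDesign, build_kernels, standardize
from fastgxe.simulate import (SimConfig, simulate_environments,
                              simulate_genotypes, simulate_phenotype)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """n=400 cohort with kernels, null phenotype (polygenic + GxE only)."""
    cfg = SimConfig(n=400, m=600, m_null=480, n_causal_main=150,
                    n_polygxe=100, q=8, h2_gxe=0.10, h2_snp=0.30, seed=7)
    geno = simulate_genotypes(cfg.n, cfg.m, cfg.maf_range, 7,
                              m_odd=cfg.m - cfg.m_null)
    X_E = simulate_environments(cfg.n, cfg.q, seed=8)
    X_std = standardize(geno.dosages)
    sim = simulate_phenotype(cfg, geno, 9, X_E=X_E, X_std=X_std)
    kern = build_kernels(X_std, X_E)
    return {"cfg": cfg, "geno": geno, "X_E": X_E, "X_std": X_std,
            "sim": sim, "kernels": kern, "design": sim.design}


@pytest.fixture(scope="session")
def null_model(small_cohort):
    from fastgxe.assoc import GxENullModel

    return GxENullModel(random_state=0).fit(
        small_cohort["design"], small_cohort["kernels"],
        gamma_genotypes=small_cohort["X_std"])


def make_design(n, q, rng, c_extra=0):
    """Plain i.i.d. design for unit tests."""
    y = standardize(rng.standard_normal(n))
    X_E = standardize(rng.standard_normal((n, q)))
    W = np.ones((n, 1))
    if c_extra:
        W = np.column_stack([W, standardize(rng.standard_normal((n, c_extra)))])
    return StandardizedDesign(sample_ids=np.arange(n), y=y, X_G=None,
                              X_E=X_E, W=W)
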