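"""Synthetic cohort generator and evaluation metrics for GxE methods.

The generator reproduces the structure of a biobank GxE study at desk
scale: independent binomial genotype dosages with odd/even chromosome
partitions (interaction effects are placed only on the odd partition so
the even partition provides clean null SNPs for type-I-error
evaluation); 40 standardized environmental factors with block
correlation emulating grouped lifestyle variables (activity, screen
time, sleep, diet, ...); and a phenotype summing

* environmental main effects               (5% of variance by default),
* polygenic SNP main effects               (30%),
* polygenic GxE effects on odd-partition SNPs, plus optionally one
  focal "power" SNP with a chosen number of active environments
  (total interaction share 15% by default),
* i.i.d. Gaussian noise                    (the remainder).

Every component is drawn Gaussian and rescaled so its realized sample
variance hits the target fraction exactly.  Active environments per
interacting SNP are drawn in two weighted stages (count, then factors
without replacement) with weights 10 for factors 1-10 and 1 for factors
11-40, so a minority of environments carries most interactions.

Evaluation helpers compute genomic inflation factors at chosen p-value
quantiles and detection power at a family-wise error rate via
Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import assoc
from .kernels import (InvalidInputError, KernelSet, StandardizedDesign,
                      compute_env_kernel, compute_grm, compute_gxe_kernel,
                      standardize)

DEFAULT_ENV_WEIGHTS = np.r_[np.full(10, 10.0), np.full(30, 1.0)]
LAMBDA_QUANTILES = (0.5, 0.05, 0.01, 1e-3, 1e-4)


class GenotypeData(NamedTuple):
    dosages: np.ndarray          # (n, m) 0/1/2
    chrom: np.ndarray            # chromosome label per SNP
    odd_partition: np.ndarray    # bool, True = odd-chromosome analog


@dataclass
class PowerSnpConfig:
    """Focal interacting SNP used for power evaluation."""

    n_active: int = 30
    var_frac: float = 0.03


@dataclass
class SimConfig:
    """Study-condition parameters for one simulation scenario.

    Defaults are the desk-scale analog of the biobank design: n=2000
    individuals, 5000 SNPs of which 4000 (even partition) are null,
    q=40 environments, 500 polygenic-GxE SNPs, 1000 main-effect SNPs,
    component variance shares (env 5%, SNP 30%, GxE 15%).
    """

    n: int = 2000
    q: int = 40
    m: int = 5000
    m_null: int = 4000
    n_causal_main: int = 1000
    n_polygxe: int = 500
    h2_snp: float = 0.30
    h2_gxe: float = 0.15
    env_var_frac: float = 0.05
    power_snp: PowerSnpConfig | None = None
    env_weights: np.ndarray = field(
        default_factory=lambda: DEFAULT_ENV_WEIGHTS.copy())
    n_masked: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)
    env_block_size: int = 5
    env_block_corr: float = 0.15
    env_types: str = "mixed"
    seed: int = 0
    n_replicates: int = 20

    def __post_init__(self):
        budget = self.env_var_frac + self.h2_snp + self.h2_gxe
        if budget > 1.0 + 1e-12:
            raise InvalidInputError(
                f"variance fractions sum to {budget:.3f} > 1")
        if self.power_snp is not None and \
                self.power_snp.var_frac > self.h2_gxe:
            raise InvalidInputError(
                "power-SNP variance exceeds total GxE budget")
        if len(self.env_weights) != self.q:
            if self.q == 40:
                raise InvalidInputError("env_weights length must equal q")
            # non-default q: keep the 10:1 split on the first quarter
            k = max(1, self.q // 4)
            self.env_weights = np.r_[np.full(k, 10.0),
                                     np.full(self.q - k, 1.0)]


@dataclass
class SimOutput:
    """One simulated replicate plus its ground truth."""

    design: StandardizedDesign
    X_E_full: np.ndarray
    truth: dict
    null_snp_mask: np.ndarray
    realized_fractions: dict


def simulate_genotypes(n: int, m: int, maf_range=(0.05, 0.5),
                       seed: int | np.random.Generator = 0,
                       m_odd: int | None = None) -> GenotypeData:
    """Independent binomial(2, f) dosages with f ~ Uniform(maf_range).

    SNPs are split between an odd and an even chromosome partition
    (evenly interleaved); odd-partition SNPs carry the simulated
    interaction effects, even-partition SNPs stay interaction-free.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise InvalidInputError("maf_range must be within (0, 0.5]")
    f = rng.uniform(lo, hi, size=m)
    dos = rng.binomial(2, f[None, :], size=(n, m)).astype(np.float64)
    if m_odd is None:
        m_odd = m // 5
    odd = np.zeros(m, dtype=bool)
    odd_idx = np.unique(np.round(np.linspace(0, m - 1, m_odd)).astype(int))
    odd[odd_idx] = True
    chrom = np.where(odd, 2 * (np.arange(m) % 11) + 1,
                     2 * (np.arange(m) % 11) + 2)
    return GenotypeData(dosages=dos, chrom=chrom, odd_partition=odd)


_ORDINAL_CUTS = (0.50, 0.80, 0.95)   # 4 skewed levels: 50/30/15/5 %
_BINARY_PREVALENCE = 0.15


def simulate_environments(n: int, q: int, block_size: int = 5,
                          block_corr: float = 0.15,
                          seed: int | np.random.Generator = 0,
                          types: str = "mixed") -> np.ndarray:
    """Standardized environments with block correlation and mixed types.

    Factors come in blocks of ``block_size`` with latent pairwise
    correlation ``block_corr`` inside a block and independence across
    blocks, emulating groups of related lifestyle measurements.  With
    ``types="mixed"`` each block holds two continuous factors, two
    skewed 4-level ordinal factors (level shares 50/30/15/5%), and one
    binary factor (prevalence 15%) — the composition of typical
    lifestyle questionnaires, whose discreteness and skew give the
    standardized columns realistic excess kurtosis.  ``types="gaussian"``
    keeps all factors continuous.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    Z = rng.standard_normal((n, q))
    if block_corr > 0 and block_size > 1:
        for start in range(0, q, block_size):
            blk = slice(start, min(start + block_size, q))
            shared = rng.standard_normal(n)
            Z[:, blk] = (np.sqrt(block_corr) * shared[:, None]
                         + np.sqrt(1 - block_corr) * Z[:, blk])
    if types == "mixed":
        from scipy.stats import norm as _norm
        cuts = _norm.ppf(_ORDINAL_CUTS)
        bcut = _norm.ppf(1.0 - _BINARY_PREVALENCE)
        for j in range(q):
            pos = j % block_size
            if pos in (2, 3):        # ordinal
                Z[:, j] = np.searchsorted(cuts, Z[:, j])
            elif pos == 4:           # binary
                Z[:, j] = (Z[:, j] > bcut).astype(np.float64)
    elif types != "gaussian":
        raise InvalidInputError(f"unknown environment types {types!r}")
    return standardize(Z)


def _weighted_active_envs(rng: np.random.Generator, weights: np.ndarray,
                          available: np.ndarray) -> np.ndarray:
    """Two-stage weighted draw: first a count, then that many factors."""
    w = weights[available]
    p_count = weights / weights.sum()
    count = int(rng.choice(np.arange(1, len(weights) + 1), p=p_count))
    count = min(count, available.size)
    p_pick = w / w.sum()
    return rng.choice(available, size=count, replace=False, p=p_pick)


def _scale_to(vec: np.ndarray, target_var: float) -> np.ndarray:
    """Rescale so the realized (population) variance equals the target."""
    if target_var <= 0:
        return np.zeros_like(vec)
    v = vec.var()
    if v <= 0:
        raise InvalidInputError("cannot scale a constant component")
    return vec * np.sqrt(target_var / v)


def simulate_phenotype(config: SimConfig, genotypes: GenotypeData,
                       seed: int | np.random.Generator = 0,
                       X_E: np.ndarray | None = None,
                       X_std: np.ndarray | None = None) -> SimOutput:
    """Draw one phenotype replicate under the configured architecture."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n, m = genotypes.dosages.shape
    q = config.q
    if X_E is None:
        X_E = simulate_environments(n, q, config.env_block_size,
                                    config.env_block_corr, rng,
                                    types=config.env_types)
    if X_std is None:
        X_std = standardize(genotypes.dosages)
    odd_idx = np.flatnonzero(genotypes.odd_partition)
    if m < config.n_causal_main + config.n_polygxe + 1:
        raise InvalidInputError("not enough SNPs for the causal sets")
    if odd_idx.size < config.n_polygxe + 1:
        raise InvalidInputError("odd partition smaller than n_polygxe + 1")

    parts: dict[str, np.ndarray] = {}
    fracs: dict[str, float] = {}

    beta_E = rng.standard_normal(q)
    parts["env_main"] = _scale_to(X_E @ beta_E, config.env_var_frac)
    fracs["env_main"] = config.env_var_frac

    causal_main = rng.choice(m, size=config.n_causal_main, replace=False)
    beta_G = rng.standard_normal(config.n_causal_main)
    parts["poly_main"] = _scale_to(X_std[:, causal_main] @ beta_G,
                                   config.h2_snp)
    fracs["poly_main"] = config.h2_snp

    polygxe_idx = rng.choice(odd_idx, size=config.n_polygxe, replace=False)
    power_frac = 0.0
    power_idx = None
    power_envs = np.array([], dtype=int)
    if config.power_snp is not None:
        power_frac = config.power_snp.var_frac
        pool = np.setdiff1d(odd_idx, polygxe_idx)
        power_idx = int(rng.choice(pool))
        avail = np.arange(q)
        w = config.env_weights
        k = min(config.power_snp.n_active, q)
        power_envs = rng.choice(avail, size=k, replace=False,
                                p=w / w.sum())
        b = rng.standard_normal(k)
        gxe = (X_std[:, power_idx][:, None] * X_E[:, power_envs]) @ b
        parts["power_gxe"] = _scale_to(gxe, power_frac)
        fracs["power_gxe"] = power_frac

    env_sets = []
    poly_gxe = np.zeros(n)
    for j in polygxe_idx:
        envs = _weighted_active_envs(rng, config.env_weights, np.arange(q))
        env_sets.append(envs)
        b = rng.standard_normal(envs.size)
        poly_gxe += (X_std[:, j][:, None] * X_E[:, envs]) @ b
    poly_target = config.h2_gxe - power_frac
    parts["poly_gxe"] = _scale_to(poly_gxe, poly_target)
    fracs["poly_gxe"] = poly_target

    noise_frac = 1.0 - config.env_var_frac - config.h2_snp - config.h2_gxe
    parts["noise"] = _scale_to(rng.standard_normal(n), noise_frac)
    fracs["noise"] = noise_frac

    y = sum(parts.values())
    realized = {k: float(v.var()) for k, v in parts.items()}

    X_E_analysis = X_E
    masked_envs = np.array([], dtype=int)
    if config.n_masked > 0:
        masked_envs = power_envs[:config.n_masked]
        keep = np.setdiff1d(np.arange(q), masked_envs)
        X_E_analysis = X_E[:, keep]

    design = StandardizedDesign(
        sample_ids=np.arange(n),
        y=standardize(y),
        X_G=None,
        X_E=X_E_analysis,
        W=np.ones((n, 1)),
    )
    truth = {
        "causal_main": causal_main,
        "polygxe_idx": polygxe_idx,
        "polygxe_envs": env_sets,
        "power_idx": power_idx,
        "power_envs": power_envs,
        "masked_envs": masked_envs,
    }
    return SimOutput(design=design, X_E_full=X_E, truth=truth,
                     null_snp_mask=~genotypes.odd_partition,
                     realized_fractions=realized)


def genomic_inflation(pvalues: np.ndarray, quantile: float) -> float:
    """Inflation factor at a p-value quantile.

    ``lambda_q = Q_chi2(1 - p_(q)) / Q_chi2(1 - q)`` where ``p_(q)`` is
    the q-th quantile of the observed p-values; 1 indicates calibration
    at that quantile.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    p = p[np.isfinite(p)]
    if p.size == 0 or np.any((p <= 0) | (p > 1)):
        raise InvalidInputError("p-values must lie in (0, 1]")
    if p.size < 1.0 / quantile:
        raise InvalidInputError(
            f"too few p-values ({p.size}) for quantile {quantile}")
    observed = np.quantile(p, quantile)
    return float(chi2.isf(observed, 1) / chi2.isf(quantile, 1))


def power_at_fwer(p_of_causal_snps: np.ndarray, m_total: int,
                  alpha_fwer: float = 0.01) -> float:
    """Fraction of causal SNPs detected at a Bonferroni FWER threshold."""
    if m_total < 1:
        raise InvalidInputError("m_total must be >= 1")
    p = np.asarray(p_of_causal_snps, dtype=np.float64)
    if p.size == 0:
        return 0.0
    return float(np.mean(p < alpha_fwer / m_total))


def run_scenario(config: SimConfig,
                 modes: str | Sequence[str] = "fastgxe",
                 seed: int | None = None,
                 quantiles: Sequence[float] = LAMBDA_QUANTILES,
                 alpha_fwer: float = 0.01,
                 scan_null: bool = True):
    """Run one simulation scenario end to end.

    Genotypes and environments are drawn once and held fixed; each
    replicate redraws effect sizes and noise, refits the null model, and
    scans.  Returns a dict with pooled genomic-inflation factors per
    mode, per-replicate metrics, and (when a power SNP is configured)
    detection power at the family-wise error rate.
    """
    if isinstance(modes, str):
        modes = (modes,)
    seed = config.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    g_rng, e_rng, *rep_seeds = root.spawn(2 + config.n_replicates)

    geno = simulate_genotypes(
        config.n, config.m, config.maf_range,
        np.random.default_rng(g_rng),
        m_odd=config.m - config.m_null)
    X_E = simulate_environments(config.n, config.q, config.env_block_size,
                                config.env_block_corr,
                                np.random.default_rng(e_rng),
                                types=config.env_types)
    X_std = standardize(geno.dosages)
    K_G = compute_grm(X_std)       # fixed across replicates and maskings
    kernels_full = None

    pooled: dict[str, list[np.ndarray]] = {mode: [] for mode in modes}
    power_p: dict[str, list[float]] = {mode: [] for mode in modes}
    rows = []
    null_idx = np.flatnonzero(~geno.odd_partition)
    rng_gamma = np.random.default_rng(root.spawn(1)[0])
    gamma_cols = rng_gamma.choice(config.m, size=min(500, config.m),
                                  replace=False)

    for rep, rs in enumerate(rep_seeds):
        rep_rng = np.random.default_rng(rs)
        sim = simulate_phenotype(config, geno, rep_rng, X_E=X_E,
                                 X_std=X_std)
        design = sim.design
        masked = sim.truth["masked_envs"]
        if masked.size:
            keep = np.setdiff1d(np.arange(config.q), masked)
            X_E_used = X_E[:, keep]
        else:
            X_E_used = X_E
        if kernels_full is None or masked.size:
            K_E = compute_env_kernel(X_E_used)
            kernels = KernelSet(K_G=K_G, K_E=K_E,
                                K_GxE=compute_gxe_kernel(K_G, K_E),
                                m_snps=config.m)
            if not masked.size:
                kernels_full = kernels
        else:
            kernels = kernels_full

        scan_cols = null_idx if scan_null else np.array([], dtype=int)
        p_idx = sim.truth["power_idx"]
        if p_idx is not None:
            scan_cols = np.r_[scan_cols, p_idx]
        dos = geno.dosages[:, scan_cols]

        null_model = None
        needs_mixed = any(mode != "vc_only_nopoly" for mode in modes)
        if needs_mixed:
            null_model = assoc.GxENullModel(
                random_state=int(rep_rng.integers(2 ** 31))).fit(
                design, kernels, gamma_genotypes=X_std[:, gamma_cols])

        results: dict[str, pd.DataFrame] = {}
        if needs_mixed:
            want_minp = "minp" in modes
            base_mode = "fastgxe" if "fastgxe" in modes else "minp"
            res = assoc.genome_scan(design, kernels, dos, mode=base_mode,
                                    null=null_model,
                                    include_env_p=want_minp)
            if "fastgxe" in modes:
                results["fastgxe"] = res
            if want_minp:
                env_cols = [c for c in res.columns if c.startswith("p_env_")]
                pm = res[env_cols].to_numpy()
                minp = res.copy()
                minp["p_gxe"] = np.where(
                    res["qc_pass"],
                    np.minimum(1.0, np.nanmin(pm, axis=1)
                               * np.sum(np.isfinite(pm), axis=1)),
                    np.nan)
                results["minp"] = minp
        if "vc_only_nopoly" in modes:
            results["vc_only_nopoly"] = assoc.genome_scan(
                design, kernels, dos, mode="vc_only_nopoly")

        n_null_scanned = null_idx.size if scan_null else 0
        for mode in modes:
            res = results[mode]
            row = {"replicate": rep, "mode": mode}
            if scan_null:
                p_null = res["p_gxe"].to_numpy()[:n_null_scanned]
                p_null = p_null[np.isfinite(p_null)]
                pooled[mode].append(p_null)
                for qq in quantiles:
                    if p_null.size >= 1.0 / qq:
                        row[f"lambda_{qq:g}"] = genomic_inflation(p_null, qq)
            if p_idx is not None:
                p_power = float(res["p_gxe"].iloc[-1])
                power_p[mode].append(p_power)
                row["p_power_snp"] = p_power
                row["detected"] = p_power < alpha_fwer / config.m
            rows.append(row)

    out = {"per_replicate": pd.DataFrame(rows), "pooled_lambda": {},
           "power": {}}
    for mode in modes:
        if scan_null and pooled[mode]:
            allp = np.concatenate(pooled[mode])
            out["pooled_lambda"][mode] = {
                qq: genomic_inflation(allp, qq)
                for qq in quantiles if allp.size >= 1.0 / qq}
        if power_p[mode]:
            out["power"][mode] = power_at_fwer(
                np.array(power_p[mode]), config.m, alpha_fwer)
    return out
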