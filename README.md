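# fastgxe

Genome-wide testing of genotype-environment interactions (GxE) across
many environmental factors at once, with the polygenic confounding
controlled that single-SNP interaction tests usually ignore.

Standard GWAS asks whether a SNP shifts a trait on average. Many SNPs
instead act context-dependently — their effect grows or shrinks with
age, diet, activity, smoking. Testing that SNP-by-environment
interaction genome-wide is statistically awkward: with q = 40
environments a joint F test is underpowered, per-environment tests lose
power when several environments interact, and *polygenic* interaction
effects spread over thousands of background SNPs act like population
stratification, inflating whatever test ignores them. This package is
for statistical geneticists who want a calibrated, scalable
multi-environment GxE scan on biobank-style data (PLINK genotypes plus
ID-keyed phenotype/environment tables), together with the follow-up
analyses that make a hit interpretable.

## Model and test

Per SNP `x_G` (all variables standardized):

    y = x_G b_G + X_E b_E + sum_k (x_G * x_E(k)) b_GxE(k) + g + v + e
    g ~ N(0, s_g^2 K_G),  v ~ N(0, s_v^2 K_G ⊙ K_E),  e ~ N(0, s_e^2 I)

`K_G = X_G X_G'/m` is the genomic relationship matrix, `K_E = X_E
X_E'/q` the environmental similarity kernel, and their Hadamard product
the covariance of polygenic interaction effects. The per-SNP test
combines q single-environment score tests `p_1..p_q` and a
variance-component test `p_v` (weighted-chi-square null, Davies-type
inversion) through the Cauchy combination

    T = 1/2 sum_k (1/q) tan((0.5-p_k)pi) + 1/2 tan((0.5-p_v)pi),
    p = 0.5 - arctan(T)/pi,

valid under arbitrary dependence. A GRAMMAR-GAMMA-style two-step
(precomputed mixed-model residuals plus one scalar calibration factor)
makes each SNP an O(nq) operation. Companion modules estimate the
interaction heritability `s_v^2/(s_g^2+s_v^2+s_e^2)` by method of
moments with randomized trace estimation, identify the driver
environments with a sum-of-single-effects model under the mixed-model
covariance (whitening + SuSiE, PIP > 0.5), and validate hits by
splitting individuals into quintiles of their aggregated interacting
environment (AIE) score and testing equality of the per-group SNP main
effects with a chi-square(4) Wald statistic.

## Worked example

Simulate a small cohort with one strongly interacting SNP, scan it, and
select its driver environments:

```python
import numpy as np
from fastgxe import (SimConfig, PowerSnpConfig, simulate_genotypes,
                     simulate_environments, simulate_phenotype,
                     standardize, build_kernels, GxENullModel,
                     genome_scan, select_environments)

cfg = SimConfig(n=1000, m=1200, m_null=900, n_causal_main=300,
                n_polygxe=200, h2_gxe=0.15, h2_snp=0.30,
                power_snp=PowerSnpConfig(n_active=5, var_frac=0.05),
                seed=0)
geno = simulate_genotypes(cfg.n, cfg.m, cfg.maf_range, 0, m_odd=300)
X_E  = simulate_environments(cfg.n, cfg.q, seed=100)
X_std = standardize(geno.dosages)
sim  = simulate_phenotype(cfg, geno, 200, X_E=X_E, X_std=X_std)
kern = build_kernels(X_std, X_E)

null = GxENullModel(random_state=0).fit(sim.design, kern,
                                        gamma_genotypes=X_std)
print(f"h2_snp={null.vc_.h2_snp_:.3f}  h2_gxe={null.vc_.h2_gxe_:.3f}")

res = genome_scan(sim.design, kern, geno.dosages, mode="fastgxe",
                  null=null)
top = res.loc[res["p_gxe"].idxmin()]
print(f"top SNP: {top['snp']}  p_gxe={top['p_gxe']:.3e}  "
      f"(truth: snp{sim.truth['power_idx']})")

sel = select_environments(null, X_std[:, sim.truth["power_idx"]])
print("selected environments:", sel.selected.tolist(),
      " truth:", sorted(sim.truth["power_envs"].tolist()))
```

Output from this exact script:

```
h2_snp=0.307  h2_gxe=0.172
top SNP: snp497  p_gxe=6.294e-09  (truth: snp497)
selected environments: [3, 39]  truth: [0, 1, 3, 20, 39]
```

The fitted variance shares are close to the simulated 30% / 15% (the
interaction share is noisy at n=1000 - a moment estimate of an
interaction variance needs large cohorts for precision); the scan ranks
the planted SNP first at a genome-wide-significant p-value; and the
selection step recovers the two environments carrying the largest
shares of the planted interaction variance, while the weaker three fall
below the PIP > 0.5 call threshold at this sample size.

There is also a command-line interface for file-based workflows:

```sh
fastgxe scan --bfile geno --pheno pheno.tsv --env env.tsv \
             --mode fastgxe --out results.tsv.gz
fastgxe finemap --bfile geno --pheno pheno.tsv --env env.tsv \
                --snp rs123 --out envsel.json
fastgxe stratify --bfile geno --pheno pheno.tsv --env env.tsv \
                 --snp rs123 --envsel envsel.json --out strat.tsv
```

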