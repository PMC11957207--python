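# Methods

## Model

For a quantitative trait `y` (n individuals), q measured environmental
factors `X_E`, and one SNP `x_G` at a time (all column-standardized to
mean 0, SD 1), the working model is

    y = x_G b_G + X_E b_E + sum_k (x_G * x_E(k)) b_GxE(k) + g + v + e

with `g ~ N(0, s_g^2 K_G)` the polygenic background, `v ~ N(0, s_v^2
K_GxE)` the polygenic genotype-environment interaction background, and
`e ~ N(0, s_e^2 I)`. The kernels are `K_G = X_G X_G' / m` (genomic
relationship matrix over m genome-wide SNPs, columns standardized with
sample SD so the diagonal averages ~1), `K_E = X_E X_E' / q`, and
`K_GxE = K_G ⊙ K_E` (Hadamard product; PSD by the Schur product
theorem). An optional sparsified GRM zeroes off-diagonal entries below a
threshold (default 0.05, the usual relatedness cutoff); for nominally
unrelated cohorts it is nearly diagonal.

The genome-wide null hypothesis per SNP is that all q interaction
coefficients vanish. Because power depends on how many environments
truly interact, the test aggregates two complementary statistics:

* q single-environment score tests of `d_k = x_G * x_E(k)`;
* one variance-component score test treating the `b_GxE(k)` as i.i.d.
  normal (statistic `Q = r' G G' r`, `G = diag(x_G) X_E / sqrt(q)`),
  whose null is a weighted sum of chi-square(1) variables.

The q+1 p-values are combined by the Cauchy rule,

    T = (1/2) sum_k (1/q) tan((0.5 - p_k) pi) + (1/2) tan((0.5 - p_v) pi),
    p = 0.5 - arctan(T)/pi,

which is level-correct under arbitrary dependence of its inputs. For
numerical safety p-values are clipped to [1e-300, 1 - 1e-16] before the
tangent; for |T| > 1 the tail is evaluated as arctan(1/T)/pi. When a
component p-value is unavailable (constant interaction predictor) its
weight is dropped and the rest renormalized to sum to one.

## Two-step scan and calibration factor

The null model (no SNP terms; covariates = intercept + user covariates
+ the q environment main effects) is fitted once. Variance components
come from a method-of-moments fit (below); then `V = s_g^2 K_G + s_v^2
K_GxE + s_e^2 I` is factorized, GLS covariate effects and generalized
residuals `r = P y` are computed, and per-environment calibration
factors

    gamma_k = mean over random SNPs of (d' P d) / (d' M0 d),
    d = x_G * x_E(k),  M0 = projector off the fixed covariates

are estimated from ~500 random SNP-environment products (a second
scalar factor over plain genotype columns calibrates the main-effect
screen). Each per-SNP score test then costs inner products only:
`z_k = d_k' r / sqrt(gamma_k d_k' M0 d_k)` (the numerator needs no
projection because `r` is exactly orthogonal to the covariates). Three
ingredients of this denominator are all essential at realistic scale:
using `d'Pd` rather than `d'V^{-1}d` in the ratio (the covariate
correction is ~2% with ~45 covariates at n=2000, and the Bonferroni
minimum over 40 tests amplifies a 2% variance overstatement into severe
median deflation); one factor per environment (skewed or discrete
exposures change the ratio systematically through the fourth moments of
x_E); and the projected norm `d'M0 d` per SNP (per-predictor covariate
alignment fluctuates by O(sqrt(c)/n), which at n <= 500 dominates the
error of any scalar calibration). The approximation is gated in the
tests by |z_approx - z_exact| <= 0.05 against the dense mixed-model
score test. The variance-component weights use the same geometry:
eigenvalues of `diag(sqrt(gamma)) G'M0G diag(sqrt(gamma))`.

SNPs whose main-effect p-value exceeds 1e-3 have `b_G` fixed at zero
(no conditioning needed); the few SNPs below the threshold get an exact
rank-one update of the projector so their interaction tests condition
on the genotype as a fixed covariate.

Tail probabilities of weighted
chi-square sums use numerical inversion of the characteristic function
(Davies/Imhof-type integral) with a per-SNP truncation point from
Imhof's bound and Gauss-Legendre panels sized to the oscillation count;
statistics more than 5.5 SD above the null mean switch to the Kuonen
saddlepoint, with Liu moment matching as last resort. With fewer than
five positive weights the integrand decays too slowly for the blocked
rule: equal-weight cases are evaluated exactly as scaled chi-squares
(this covers q=1, where the test coincides with the squared
single-environment z) and unequal small-q cases use the saddlepoint.

## Variance components and interaction heritability

The three components solve the 3x3 moment system matching
`y'K_G y`, `y'K_GxE y`, `y'y` to their expectations. Fixed covariates
are projected out of both the phenotype and the kernels (`A = P0 K
P0`), with the identity block replaced by the projector (trace n - c).
Traces of kernel products are computed exactly for dense kernels
(`tr(AB) = sum(A*B)`, O(n^2)); the Hutchinson randomized estimator
(`tr(K1 K2) = E[w' K1 K2 w]`, standard-normal probes, s=30 by default,
Rademacher probes optional) is retained as the scalable path. Negative
solutions are clipped to zero and the reduced square subsystem
re-solved. Interaction heritability is `h2_gxe = s_v^2 / (s_g^2 + s_v^2
+ s_e^2)`. Probe noise propagates into the solution through the
system's condition number (~20-120 depending on q), so component
accuracy is roughly an order of magnitude looser than trace accuracy.

## Environment selection (mixed-model sum of single effects)

For a significant SNP, the trait is residualized on the SNP (ordinary
regression with intercept), the q interaction predictors form
`X_GxE = diag(x_G) X_E`, and the mixed model is reduced to ordinary
regression by whitening with the symmetric eigen square root of
`Sigma = s_g^2 K_G + s_v^2 K_GxE + s_e^2 I` (variance components reused
from the genome-scan null fit; a near-singular Sigma receives a 1e-8
ridge and a warning). On the whitened data a sum-of-single-effects
(SuSiE) model with L=10 effects is fitted by iterative Bayesian
single-effect coordinate ascent: per effect, the prior variance is
optimized by empirical Bayes on the single-effect marginal likelihood
and the effect is switched off unless the optimum beats the null by
0.1 nats (without this check, many weakly-positive effects accumulate
uniform inclusion mass and null PIPs drift toward 1 - (1-1/q)^L);
switched-off effects are excluded from the posterior inclusion
probabilities `PIP_j = 1 - prod_l (1 - alpha_lj)`. The ELBO is
non-decreasing per sweep and convergence is declared when its change
falls below 1e-4. Credible sets use 95% coverage with purity pruning at
minimum absolute correlation 0.5. Environments with PIP > 0.5 are
declared drivers.

## Stratified validation

Per-individual aggregated interacting-environment (AIE) scores
`X_E b_hat` (posterior means from the selection step) define five
rank-based groups of near-equal size (ties broken by stable input
order; the first n mod 5 groups take the extra samples). Within each
group the SNP main effect is re-estimated by a linear mixed model with
the subsetted GRM (a two-component moment fit followed by GLS; with no
relatedness this reduces to OLS, and groups smaller than the covariate
count + 11 are skipped). Group significance uses 1e-8 (5e-8 adjusted
for five groups). Heterogeneity is tested with
`W = (R b)' [R diag(se^2) R']^{-1} (R b)` where R holds successive
differences; W is chi-square with (groups - 1) degrees of freedom, and
is invariant to any full-rank reparameterization of the contrast rows.
Group covariances are treated as diagonal because the groups are
disjoint samples.

## Synthetic study conditions

The generator mirrors a biobank GxE simulation design at desk scale.
Genotypes are independent binomial(2, f) dosages, f ~ U(0.05, 0.5),
with SNPs split into an odd and an even chromosome partition; all
simulated interaction effects sit on the odd partition so the even
partition yields clean null SNPs. Defaults: n=2000, m=5000 SNPs (4000
null), q=40 environments, 1000 main-effect SNPs, 500 polygenic-GxE
SNPs, variance shares 5% environment main effects, 30% SNP heritability
{5, 30, 50}% configurable, and total interaction share {5, 15, 25}%.
Each component is drawn Gaussian and rescaled so its realized sample
variance equals the target exactly. Active environments per interacting
SNP are drawn in two weighted stages (a count, then that many factors
without replacement) with weights 10 for factors 1-10 and 1 for factors
11-40. Power scenarios add one focal SNP whose interaction share is
{2, 3, 4}% by default: at n=2000 these reproduce the signal-to-threshold
regime (non-centrality n x share against a Bonferroni cut of
0.01/m) of the full-scale design, whose per-SNP shares of 0.1-0.25%
only separate methods at biobank sample sizes. Twenty replicates per
scenario redraw effects and noise while genotypes and environments stay
fixed, emulating a study that simulates many phenotypes on one real
cohort.

Environmental factors are generated in eight blocks of five with latent
within-block correlation 0.15, and each block holds two continuous, two
skewed four-level ordinal (50/30/15/5%), and one binary (prevalence
15%) factor before standardization. This mimics the composition of
lifestyle questionnaires - grouped, modestly correlated, mostly
discrete and skewed. Both properties matter for calibration studies:
the correlation controls how far the Bonferroni-minimum comparator
deflates at the median, and the excess kurtosis of discrete factors is
what lets unmodeled polygenic interaction variance inflate the
no-polygenic-control comparator. What the generator does **not**
emulate: linkage disequilibrium between SNPs, population stratification
and relatedness, environment-ancestry correlation, and measurement
error in exposures. Passing calibration here therefore demonstrates
correctness of the statistical machinery under the modeled
architecture, not robustness to confounding that only real genotype
data exhibit.

Evaluation metrics: the genomic inflation factor at quantile t is
`lambda_t = Q_chi2_1(1 - p_(t)) / Q_chi2_1(1 - t)` with `p_(t)` the
t-quantile of pooled null p-values (p-values pooled across replicates
rather than averaging per-replicate factors); power is the fraction of
causal-SNP p-values below a Bonferroni family-wise threshold
(default 1% over the number of SNPs).

## Numerical and design notes

* Genotype QC in the scan: minor allele frequency >= 0.01, missingness
  <= 5%, per-SNP mean imputation before standardization; monomorphic
  columns are flagged and skipped.
* Moment-system singularity (e.g. identical kernels) raises a
  degenerate-model error rather than returning unstable estimates.
* The combined test's median inflation factor is intrinsically below 1
  because the variance-component statistic is built from the same score
  vector as the single-environment tests; the Cauchy rule keeps the
  tail calibrated under this dependence while the center is
  conservative. In our implementation the pooled median factor settles
  near 0.85-0.89 (tails 0.98-1.03), somewhat more conservative at the
  median than the reference two-variance-component implementation this
  package follows; the gap is insensitive to how the
  variance-component p-value is computed (exact inversion vs moment
  matching change it by < 0.002) and reflects the dependence structure
  of the component tests rather than a tolerance choice.
* Rank-based inverse-normal transform uses offset 0.5: scores are
  `Phi^{-1}((rank - 0.5)/n)`, ties averaged.
* PLINK 1 bed I/O is SNP-major only; dosages count the A1 allele; the
  2-bit code 01 is missing.
* All randomized steps (trace probes, calibration predictor draws,
  simulation replicates) take explicit seeds; scenario orchestration
  derives per-replicate seeds from one root `SeedSequence`.
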