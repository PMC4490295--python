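# Methods

This note documents the statistical model, the estimators, the
synthetic-data generator and the numerical choices behind `phenofactor`,
in the package's own terms.  Nothing here asserts an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Measurement model

The phenotype is measured by p = 26 ordinal indicators mapped 6/7/6/7 to
four symptom domains (somatic, social dysfunction, anxiety, depression).
Twenty-four indicators carry 4 ordered categories (Likert 0–3); two —
"headaches" and "sleep problems" — are composites of two highly
correlated raw items and carry 7 categories (0–6).  Composites are
modelled directly as single 7-category ordinal indicators: the analysis
only ever sees the composite, and treating it as one indicator avoids
the collinearity that motivated compositing in the first place.

Under the graded-response (two-parameter normal-ogive) model with theta
parameterization, indicator j has a continuous latent response

    y*_j = λ_g,j η_g + λ_s,j η_s(j) + ε_j,   ε_j ~ N(0, 1),

and the observed category counts the thresholds τ_j,k below y*_j.  The
**bi-factor** structure gives every indicator one general and exactly one
specific loading with all factor covariances fixed at zero; the
**first-order** structure drops the general factor and frees the six
domain correlations; the **baseline** (independence) model has no
loadings and anchors the incremental fit indices.

Degrees of freedom follow the limited-information convention: thresholds
are saturated against the marginal proportions, so
df = p(p−1)/2 − (free loadings + free factor correlations).  For the
bi-factor model, 325 − 52 = 273; first-order, 325 − 32 = 293;
baseline, 325.

## Sample statistics

Thresholds are the probit transforms of cumulative marginal proportions.
Polychoric correlations use two-step maximum likelihood: thresholds fixed
at their marginal estimates, then a bounded scalar search (tolerance
1e-10, bounds ±0.999) maximises the bivariate-normal cell-probability
likelihood.  The bivariate normal CDF is evaluated through Owen's T
function (vectorised over cell corners; exact zeros in the arguments are
nudged by 1e-13, infinite thresholds clipped at ±8.5, both far below the
accuracy of the T evaluation).  Polyserial correlations (item × genotype)
use the analogous ordinal-given-continuous probit likelihood with the
genotype standardised; its three-point support is accepted as-is.
Asymptotic variances are inverse observed information of the second-step
likelihood (central differences, h = 1e-4); they serve only as DWLS
weights, never for inference on the correlations themselves.
Estimation is complete-case by default, matching an analysis restricted
to subjects with complete data; a pairwise-complete mode exists for
exploration.  The assembled matrix is eigenvalue-clipped to positive
semi-definite (floor 1e-6) only if its smallest eigenvalue is below
−1e-8, with pre/post eigenvalues logged.

## DWLS estimation

With s the vector of sample polychoric (plus, for MIMIC fits,
item-genotype polyserial) correlations and σ(θ) the model-implied
correlations — Λ A Λ′ + I on the latent-response scale, rescaled to the
correlation metric — the estimator minimises

    F(θ) = Σ_m w_m (s_m − σ_m(θ))²,   w_m = 1 / (n · avar_m),

by L-BFGS-B with the analytic gradient of σ (rank-one structure per
loading), deterministic start values (general loadings 0.5, specific
0.3, factor correlations 0.3, SNP paths 0), gradient tolerance 1e-8 and
at most 500 iterations.  Loading signs are indeterminate; after fitting,
each factor's loading column is flipped if its sum is negative, with the
factor's SNP path and correlations flipped to match.  Non-convergence
returns a flagged result with diagnostics rather than raising.

The test statistic is χ² = (n−1)·F̂.  A mean-scaled (Satterthwaite-type)
statistic would divide by tr(U·Γ)/df, where Γ is the asymptotic
covariance of s; this package approximates Γ by its diagonal (estimating
the full matrix is out of scope), and with weights equal to the inverse
diagonal the scaling factor is identically 1, so χ² is reported
unscaled.  Two consequences, stated plainly: the χ² is calibrated only
approximately (in simulations it tends to run below its df, because the
two-step asymptotic variances ignore threshold estimation error and
moment correlations), and parameter standard errors collapse to the
simple form sqrt(diag((Δ′WΔ)⁻¹)/(n−1)).  Empirically the γ standard
errors track the Monte-Carlo sampling spread of γ̂ well (checked in the
test suite via null calibration and power runs); the χ²-based indices
should be read as descriptive.  Fit-index formulas:
RMSEA = sqrt(max(χ²−df,0)/(df·(n−1))), CFI with the standard max(·,0)
guards, TLI from the χ²/df ratios.  The conventional cutpoints
(CFI/TLI 0.90/0.95; RMSEA 0.05/0.08) appear only as report annotations.

## MIMIC SNP association

The genotype (additive minor-allele count, standardised) enters as an
observed cause of the factors: η_f = γ_f g + ζ_f with Var(η_f) = 1, so
Var(ζ_f) = 1 − γ_f² and the model-implied item-genotype correlation is
(Λγ)_j / sd(y*_j).  In the bi-factor model the disturbances stay
orthogonal while the shared cause induces factor covariance γ_f γ_f′;
in the first-order model the total factor correlations remain the free
parameters.  Loadings and all five (four) SNP paths are estimated
simultaneously; the effect size is r² = 100·γ_f² percent of factor
variance, and the Wald z = γ̂/se(γ̂) gives the per-factor test.  A
constrained refit with selected paths fixed at zero is available
(`fix_gamma_zero`), which returns r² = 0 exactly for those factors.

One SNP is analysed at a time.  QC drops SNPs with call rate ≤ 0.90 or
minor allele frequency ≤ 0.05 before analysis, with a per-SNP reason
report.  No multiple-testing correction is applied by default (candidate
SNPs are taken as chosen a priori; a Benjamini–Hochberg helper exists).
Effect-size distributions across SNPs are summarised by a Gaussian KDE
(Silverman bandwidth with a small floor so degenerate inputs produce a
narrow peak; curves integrate to 1 within 1e-3).

A deliberate omission: there is no two-step "factor score then regress"
mode.  Estimating the SNP paths inside the measurement model is the
point of the latent approach; factor-score regression reintroduces the
measurement-error attenuation the method exists to avoid.

## Synthetic-data generator

The generator is first-class, tested code and defines the study
conditions for every stochastic check.  Genotypes are Hardy–Weinberg
draws (minor-allele count ~ Binomial(2, MAF), default MAF 0.3).  For a
target fraction R² of a factor's variance, the centred genotype receives
coefficient sqrt(R²/var(g)) (empirical variance, so the factor's unit
variance and the R² interpretation are exact by construction) and the
disturbance variance shrinks to 1 − R².  Defaults: n = 1337 subjects
(the complete-case size the comparison design anchors on), 26 indicators
with the 6/7/6/7 mapping and the two 7-category composites.

Default loadings are **synthetic** — the source cohort's item parameters
are not publicly deposited — and are fixed heterogeneous values (general
0.5–1.3, specific 0.3–1.1) whose general/specific ratio varies from item
to item within each domain, as item-level bi-factor fits of real symptom
scales show.  This heterogeneity is also an identification requirement:
if every item in a domain shared the same pair of loadings, the four
specific columns of Λ would sum to a multiple of the general column and
the five SNP paths of the MIMIC model would be collinear (the partialled
Fisher information for a specific path goes to zero).  The
near-homogeneous regime is therefore both unrealistic and statistically
degenerate, and the defaults avoid it by design.  Thresholds are set via
target cumulative marginals to give right-skewed symptom distributions,
most extreme for depression items (≈85% in the lowest category), so the
generated sum scores reproduce the qualitative pattern of real GHQ-type
data: a strongly right-skewed depression subscale (sample skewness ≈ 3),
milder skew elsewhere.

The generator emits complete data by default; an MCAR `missing_rate`
flag supports testing the complete-case filter.  A multi-SNP variant
(`simulate_cohort`) lets several independent SNPs act additively on the
factors (their per-factor R² must sum below 1).  What the generator does
**not** emulate: linkage disequilibrium, haplotypes, population
stratification, non-MCAR missingness, direct SNP→item effects,
group-varying measurement, or any real cohort's parameter values.
Passing tests therefore demonstrate internal validity of the estimators
under the assumed data-generating process, not agreement with any real
cohort's estimates.

## Power analysis

Post hoc power fixes the effect size and sample size (n = 1337 by
default) and averages two-sided rejections at α = 0.05 over Monte-Carlo
replicates (1000 by default; genotypes are redrawn each replicate, an
assumption the design leaves open; per-replicate seeds spawn
deterministically from the master seed, so results are independent of
scheduling).  For the sum-score arm the closed-form oracle
power = P(|Z + sqrt(nf²)| > z_{1−α/2}), f² = R²/(1−R²), is the
documented reference the stochastic estimate must match within
Monte-Carlo error; at R² = 0 it equals α exactly.  For the latent arm
power is the Wald rejection rate of the targeted SNP path, with
non-converged replicates excluded and counted (more than 20% flags the
result unreliable).

## Problem sizes used by the test suite

Simulation-heavy checks use sizes chosen to keep the default suite
practical while leaving Monte-Carlo error well inside the asserted
margins: loading-recovery bias uses 50 cohorts of n = 2000; the
latent-versus-sum comparison uses 50 paired replicates at n = 1337 with
a specific-factor R² of 2% — inside the 1.1–5.2% range of the largest
effects the design targets, and chosen from the analytic noncentrality
calculation so that neither arm's power saturates at 1.0 (the sum-score
arm lands near 0.7, the latent arm near 0.99, making the direction
comparison informative); the 5.153% effect-size recovery check runs one
cohort at n = 10⁴; null calibration of the latent Wald test uses 40
replicates; latent power estimation in the wrapper test uses 100
replicates at n = 700.  Large-sample estimator checks (polychoric,
polyserial, thresholds) use n = 10⁵ with 3-standard-error bands.

## Known limitations

* The χ² scaling of full WLSMV (mean-and-variance adjustment with the
  estimated moment covariance) is not implemented; only df is treated as
  exactly reproducible across software.
* Diagonal-weight DWLS is less efficient than full-weight WLS; the SNP
  path estimator inherits this, which matters most when domain loadings
  are close to homogeneous (see the identification note above).
* Asymptotic variances of the correlations ignore first-step threshold
  uncertainty (standard two-step practice).
* The polyserial treats the genotype as continuous; with three support
  points this is an approximation, adequate for MAF > 0.05.
* No GWAS-scale batching: fits are per-SNP and the item polychorics are
  cached across SNPs, but the design targets candidate panels
  (hundreds of SNPs), not genome-wide scans.
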