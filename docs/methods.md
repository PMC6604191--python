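# Methods

This note documents the statistical models implemented in `methlink`, the
generative model behind the synthetic cohorts, the numerical choices, and
the package's known limitations. It describes what the code computes;
every number quoted here is produced by the test suite or the acceptance
script at run time.

## Exposure definition and per-cohort EWAS

The exposure is sustained maternal smoking during pregnancy, coded 1 when
the mother smoked at least one cigarette per day through pregnancy, else
0. For each CpG j the cohort-level model is ordinary least squares

    beta_ij = b0 + b1 * smoke_i + covariates_i' g + e_ij

on untransformed beta values (methylated fraction in [0, 1]); effects are
therefore in absolute methylation units. Two-sided P values use the t
distribution with the residual degrees of freedom. Because the design is
shared across CpGs, all fits come from one QR decomposition of the design
matrix; CpGs with missing values fall back to per-CpG complete-case fits,
and zero-variance CpGs are skipped and logged. Rank-deficient designs are
rejected with the offending columns named (pivoted QR).

Variants:

* **Never-smoker subset** (`restrict_never_smokers`): participants with
  own regular smoking are removed and the own-smoking covariate is
  dropped (it is constant in the subset).
* **Dose-response** (`fit_dose_response`): methylation is standardized to
  zero mean and unit SD per CpG, regressed on cigarettes/day in the full
  cohort (unexposed mothers contribute dose 0), and the per-cigarette
  slope is multiplied by 3 — the reporting convention is SD of
  methylation per three additional cigarettes per day.
* **Negative control** (`fit_negative_control`): three fits per CpG —
  maternal exposure, paternal exposure, and maternal adjusted for
  paternal. Paternal smoking shares the household environment with
  maternal smoking but has no intrauterine path, so similar effect sizes
  for both parents would indicate confounding rather than a biological
  effect.

Complete-case analysis is used throughout; dropped-sample counts are
logged. No genomic-control or surrogate-variable correction is applied.

## Meta-analysis and region pruning

Cohort estimates are pooled by fixed-effects inverse-variance weighting:
w_i = 1/SE_i², pooled beta = Σw_i b_i / Σw_i, pooled SE = (Σw_i)^(−1/2).
Meta-level P values use the standard normal (the conventional IVW choice;
per-study degrees of freedom are not propagated — at cohort sizes in the
hundreds the difference from t is negligible). CpGs observed in a subset
of cohorts are pooled over that subset with the count recorded. Cochran's
Q is computed and reported per CpG but never gates inclusion.

Significance is declared at P < 1 × 10⁻⁷ (strict inequality), the
conventional epigenome-wide level approximating a Bonferroni correction
for 450k tests. Significant CpGs are partitioned into regions greedily:
repeatedly take the unassigned CpG with the smallest P as a region
leader and absorb all unassigned CpGs on its chromosome within 500 kb
(half of the 1-Mb window). P ties — which occur in published tables
rounded to two significant figures — are broken by descending |beta/SE|,
a finer proxy for association strength than the rounded P, then by
(chromosome, position) so the partition is deterministic and independent
of input order.

**Fixture and a documented discrepancy.** Applied to the bundled table of
69 published maternal-smoking CpGs, the rule yields exactly 36 regions,
matching the published region count, and each of the 36 published leading
CpGs falls in a distinct computed region. However, in three regions
(around MYO1G, AHRR, and FRMD4A) the published lead is *not* the
smallest-P member of its region in the same published table — e.g. the
published MYO1G lead prints P = 1.2e-31 while a CpG 449 bp away prints
P = 2.6e-54. The strongest-association rule therefore cannot reproduce
those three choices from the printed data, and the corresponding
leader-identity check in the acceptance suite fails by design; the other
33 leaders match.

## Persistence across timepoints

Methylation at each timepoint is first residualized on technical
covariates and white-blood-cell proportions (one cell type dropped as the
reference, since proportions sum to 1). The residuals from both
timepoints are stacked and modelled per CpG as

    r_it = b0 + b_E * smoke_i + b_T * t + b_ET * smoke_i * t + covariates + e_it

with t ∈ {0, 1}. The errors of one individual are allowed to be
correlated across timepoints and heteroskedastic between them
(unstructured 2×2 covariance: two variances and one correlation),
estimated by iterated feasible GLS — residual moments and whitened least
squares alternate until the coefficients change by less than 1e-8
relative, with a cap of 100 iterations (non-convergence is flagged per
CpG). The timepoint-1 effect is b_E, the timepoint-2 effect b_E + b_ET,
and the test of equal effects is the (normal) test of b_ET = 0.
Individuals observed at only one timepoint are retained; their error
block is the corresponding 1×1 variance. With a fully balanced panel the
stacked model is a seemingly-unrelated regression with identical
regressors, so the GLS estimates coincide with per-timepoint OLS — a
property the test suite checks.

The two-stage residualize-then-model procedure is retained deliberately
(a one-stage model including the technical covariates directly is
statistically cleaner but changes the estimand slightly); the covariates
argument of `fit_gls_persistence` provides the one-stage route when
wanted.

## Two-sample Mendelian randomization

Instruments are mQTL SNPs at P < 10⁻⁷, thinned by greedy clumping in
ascending P: a retained SNP removes remaining candidates within 500 kb
(same chromosome) that have r² ≥ 0.001 with it. Exposure and outcome
records are aligned to the same effect allele; swapped or strand-flipped
records have the outcome beta negated and frequency complemented, and
palindromic SNPs (A/T, C/G) whose effect-allele frequency lies in
[0.42, 0.58] are excluded as strand-unresolvable. With one instrument the
causal effect is the Wald ratio β_GD/β_GE; with two or more it is
fixed-effects IVW, algebraically the inverse-variance pooling of the
per-SNP ratios (first-order weights) and equivalent to a zero-intercept
weighted regression of outcome betas on exposure betas.

Standard errors: the default is the first-order SE (SE_GD/|β_GE|),
matching common two-sample MR practice; the delta-method SE
(sqrt(SE_GD²/β_GE² + β_GD² SE_GE²/β_GE⁴)) is available via
`se_method="delta"` and is the appropriate choice when instrument
uncertainty is non-negligible — at the simulated sample sizes
(mQTL n = 1000, GWAS n = 50,000) the instrument error dominates and only
the delta SE attains nominal interval coverage, which is how the
acceptance suite tests coverage. FDR control is global Benjamini–Hochberg
across all CpG × trait pairs in a scan. An optional consistency filter
drops instruments whose mQTL effect changes sign across supplied
life-course timepoint tables.

Out of scope: MR-Egger, weighted-median and other pleiotropy-robust
estimators, and colocalization; the mQTL and GWAS services are emulated
by input files.

## Causal mediation

The mediator model (CpG ~ exposure + covariates, OLS) and outcome model
(outcome ~ exposure + CpG + covariates; OLS or maximum-likelihood
logistic) are fitted on complete cases with HC1 sandwich covariances.
`quasi_bayesian_mediate` draws 2000 coefficient vectors (default) from
the independent normal approximations around the two fits. Per draw, in
the linear no-interaction case, ACME = a·b, ADE = c, and TE = ACME + ADE
exactly (potential-outcome contrasts reduce to the product of
coefficients); for logistic outcomes, mediator potential values are
simulated with the estimated residual SD and pushed through the outcome
model, and the contrasts are averaged over the sample and both exposure
arms on the probability (risk-difference) scale. Point estimates are
means over draws, intervals are 2.5/97.5 percentiles, and P values are
two-sided simulation tails. No exposure×mediator interaction is included
by default.

The proportion mediated is summarized as the **median of the per-draw
ratio** ACME/TE with a percentile interval — ratios of means are unstable
when TE is near zero — with the ratio-of-means variant also reported and
an instability flag raised whenever the TE interval covers zero or the
ACME and TE point estimates disagree in sign.

## Synthetic-data generator

`simulate_cohort` draws, per individual: a latent bivariate-normal
household environment thresholded to give maternal (prevalence 0.18) and
paternal (0.35) smoking indicators with a latent correlation of 0.4;
cigarettes/day for exposed mothers from a zero-truncated Poisson with
mean 3 (unexposed fixed at 0); own smoking (0.54), sex, BMI, social
class, age, four genetic PCs, ten technical PCs, and six
white-blood-cell proportions from a Dirichlet with granulocyte-dominant
weights. Methylation is generated directly on the beta-value scale:

    beta_ij = mu_j + effect_j*smoke_i + slope_j*cigs_i
              + covariate loadings + cell-type loadings + N(0, noise_sd)

clipped to [0, 1], with mu_j ~ U(0.15, 0.85) and noise_sd defaulting to
0.02 beta units — clipping events are logged and stay below 0.1% at the
defaults. Planted effect sizes in examples and tests are on the
0.005–0.08 beta-unit scale reported for smoking-associated CpGs; the
published work does not state per-CpG variances, so the noise default is
the package's own choice, set so effects of that magnitude are detectable
at meta-analysis sample sizes in the low thousands. Paternal smoking has
*zero* direct effect on methylation — only the shared environment links
it to the exposure — which is precisely the negative-control assumption.
The second timepoint scales each planted effect by its persistence
fraction, redraws technical covariates and cell proportions, advances age
by 16 years, and correlates residuals within individual at 0.5 with a
1.2× noise scale (heteroskedastic between timepoints). Outcomes follow
the mediation path structure: direct exposure effect plus CpG effects
plus noise, continuous (linear) and binary (liability threshold at 10%
prevalence).

`simulate_mr_inputs` emits mQTL and GWAS summary tables with sampling
error appropriate to stated sample sizes (se = (2p(1−p)n)^(−1/2)), valid
instruments only (SNP→outcome effect = causal effect × SNP→CpG effect,
no direct path), random allele pairs and frequencies, and an LD matrix
that is exchangeable within each CpG's instrument set (unit diagonal,
positive semidefinite). A `summary_noise=False` switch gives exact
product identities for oracle tests.

Every planted quantity is mirrored in a `TruthRecord` so the downstream
estimate has a ground-truth counterpart.

**What the generator does not emulate:** array intensities and probe
chemistry, probe-type or batch artifacts, realistic LD blocks, genetic
confounding of own smoking, non-Gaussian methylation error, or selection
into cohorts. Passing tests therefore demonstrate correctness of the
estimators under the assumed generative model, not robustness to the
artifacts of real array data (which enter the real analysis through the
upstream QC pipeline, out of scope here).

## Problem sizes and numerical choices

The calibration and recovery checks use: 5000 CpGs at n = 400 for EWAS
type-I error; 200 seeds for MR coverage; n = 5000 with 2000 draws for
mediation point recovery and 200 replicates at n = 2000 for ACME interval
coverage; 200 replicates at n = 2000 for the persistence equality-test
size and 50 seeds at n = 1500 for half-persistence recovery. These sizes
give Monte-Carlo error comfortably inside the asserted bands while
keeping the suite quick to run.

Floats are serialized to TSV at 17 significant digits so write/read
round-trips are exact; genomic positions are 1-based; chromosome labels
are strings without a "chr" prefix. The master seed deterministically
spawns per-stage seeds (numpy `SeedSequence`), so any stage can be rerun
in isolation and the full pipeline is byte-reproducible.

## Known limitations

* The leading-CpG rule cannot reproduce 3 of the 36 published leads (see
  above); the region count and the remaining 33 leads are reproduced.
* Published per-CpG FDR values from the MR scan are not reproduced: the
  published FDR column is not a Benjamini–Hochberg transform of its own
  printed raw P values under any single family size, so the package
  applies conventional global BH across the scan and documents the
  difference.
* First-order Wald SEs undercover when instrument uncertainty is
  substantial; use `se_method="delta"` in that regime.
* At most two timepoints; no growth-curve trajectories.
* Binary mediation outcomes are summarized on the risk-difference scale,
  not odds ratios.
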