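# Methods

## The problem

Pregnant women carry measurable concentrations of dozens of
endocrine-disrupting chemicals (EDCs) simultaneously. Estimating the
association of each chemical with infant birth weight by separate
regressions invites false positives and unstable estimates, because
chemicals within a class (e.g. the 23 PCB congeners) are strongly
positively correlated. `edcmix` implements the hierarchical-shrinkage
answer to this problem: a single linear model containing all exposures,
whose per-chemical coefficients are partially pooled toward class-level
means, alongside a penalized-regression comparison arm, a preprocessing
pipeline for censored biomarker panels, and a synthetic-cohort
generator that makes the whole analysis testable without access to
individual-level cohort data.

## The hierarchical model

For participant *i* with birth weight `y_i` (grams):

    y_i = b0 + sum_j bx_j X_ij + sum_k bc_k C_ik + f(GA_i) + e_i,
    e_i ~ N(0, sigma_res^2)

* `X_ij`: standardized visit-averaged log10 concentration of chemical
  *j* (53 chemicals in five classes: phthalates+BPA, PFAS, PCBs,
  PBDEs, organochlorine pesticides),
* `C_ik`: demographic covariates plus the non-hierarchical chemicals
  (the two organophosphate metabolites DEP and DMP, lead, mercury —
  themselves log10-standardized),
* `f(GA)`: a natural cubic spline in gestational age (default 3 df,
  boundary knots at the data range, interior knots at quantiles; the
  basis is orthogonalized against the constant so it can sit next to
  the intercept),
* exposure coefficients are exchangeable within class:
  `bx_j ~ N(mu_beta[c(j)], sigma_beta[c(j)]^2)`.

Priors: `mu_beta ~ N(0, 1e5)` and `sigma_beta ~ N(0, 1e5)` truncated
to positive values — "variance 1e5" read literally, i.e. SD ≈ 316 g,
which is vague on the scale of plausible class effects (tens of
grams). The intercept, covariate and spline coefficients get
`N(0, 1e5)` priors, and the residual SD a half-normal prior with scale
1000 g (wide relative to the ≈600 g SD of birth weight). All prior
settings are exposed in `BHLMSpec`.

Because every exposure is standardized, `bx_j` is grams per SD of
log10 concentration. Dividing a chemical's posterior draws by its
`sd_log10` re-expresses the effect as grams per 10-fold concentration
increase; class means are rescaled by the class average of member
`sd_log10` values. Both scales are always emitted, since class-level
effects are conventionally reported per 10-fold increase while the
model operates per SD.

## Posterior computation

The contract is the posterior, not the algorithm. The sampler is
blocked Gibbs:

1. the full coefficient vector has a multivariate-normal conditional,
   sampled exactly via Cholesky factorization of the posterior
   precision (the Gram matrix is precomputed once per fit);
2. each class mean `mu_beta` is conjugate normal;
3. each class SD `sigma_beta` and the residual SD are updated by
   univariate slice sampling (stepping-out with shrinkage) on their
   log-conditionals;
4. each iteration then interweaves a non-centered update: holding the
   standardized deviations `eta_j = (bx_j - mu)/sigma` fixed, the pair
   (`mu_beta`, `sigma_beta`) is redrawn from its Gaussian conditional
   (exact truncated-normal draw for the SD) and the coefficients are
   mapped back. This ancillarity-sufficiency interweaving step breaks
   the funnel-shaped coupling between a class SD and its coefficients;
   without it, `sigma_beta` mixes an order of magnitude more slowly
   (bulk ESS ≈ 50 vs ≈ 400 at 2 chains x 1,200 iterations on a
   250-participant cohort).

Two chains with over-dispersed starts are run by default; split R-hat
and bulk ESS are computed per parameter (via ArviZ) and a run fails its
convergence gate when any R-hat exceeds 1.05. The reference analysis
budget for this model family is 2 chains x 20,000 iterations with 500
warmup (`FULL_SCALE_SAMPLER`); the package default is 2 x 2,000 with
500 warmup, which on these cohort sizes (n ≈ 250–300, ≈ 75 columns)
yields R-hat ≤ 1.01 and bulk ESS well above 300 in a few seconds, so
the routine budget is adequate and the full budget is an option rather
than a need.

With hyperparameters held fixed the coefficient posterior is Gaussian
in closed form (`conjugate_posterior_fixed_hyper`); the sampler is
verified against it (and against a brute-force grid integration on a
two-parameter instance) rather than against another MCMC code.

Summaries are equi-tailed 95% and 50% credible intervals using the
standard empirical quantile definition with linear interpolation
(`numpy.quantile` defaults); intervals excluding zero are flagged at
each level.

## Penalized comparison arm

The elastic net minimizes

    (1/2n) ||y - b0 - Z b||^2
      + lambda * sum_j pf_j * (alpha |b_j| + (1-alpha)/2 b_j^2)

by cyclical coordinate descent with covariance updates and warm starts
along a 100-point log-spaced grid from `lambda_max` (computed after
projecting out the unpenalized columns) down to 0.001 x `lambda_max`;
convergence at max coefficient change < 1e-7. Exposure columns carry
penalty factor 1, confounders 0 — confounder coefficients are never
shrunk or selected away, matching how confounders are conventionally
protected in penalized exposure models. `alpha = 1` is the LASSO;
the elastic-net default `alpha = 0.5` is a conventional midpoint (the
mixing value is exposed in config since no single value is canonical).
The penalty is chosen by 10-fold cross-validation with the
minimum-mean-error rule (deterministic folds given the seed), and the
selected exposures are refit by OLS together with all confounders for
mutually adjusted estimates with standard intervals.

The solver is cross-checked against an independent in-repo
proximal-gradient (ISTA) solver and against R's glmnet. One glmnet
subtlety worth recording: with `standardize=FALSE` and a user-supplied
lambda, glmnet's internal response standardization makes the effective
ridge penalty `lambda*(1-alpha)/sd(y)` while the L1 part stays
`lambda*alpha`; the cross-check test maps that pair into this package's
parameterization (pure LASSO agrees to 1e-9 with no correction).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with every default chosen once from the packaged catalog and the study
population's published marginals:

* **Concentrations.** Each chemical's participant-level latent log
  concentration is exactly `N(ln GM, ln GSD)` from the catalog.
  Cross-chemical dependence comes from a Gaussian copula with a
  block-exchangeable correlation matrix: 0.5 within class, 0.1 between
  classes. (The source study showed only a qualitative heat map of
  pairwise correlations, so these two numbers are the package's own
  stand-in for "chemicals within a class tend to be positively
  correlated"; both are config fields.)
* **Visits.** Phthalates/BPA and the metals are measured at two
  gestational visits, the other classes once. Visit values share the
  participant latent value plus independent log-scale noise sized so
  corr(visit1, visit2) = 0.6 (`visit_icc`; no repeat-measure
  reliability was published, 0.6 is typical of urinary biomarkers).
  The per-class visit count is configurable.
* **Censoring.** Values strictly below the chemical's LOD are flagged
  censored but stored at their true value, so the downstream LOD/sqrt2
  substitution is testable against truth. Values exactly at the LOD
  count as detected. The catalog stores LODs as printed in the source
  table; for the lipid-normalized classes (PCBs, PBDEs, OCPs) the
  printed LODs are in pg/g against ng/g concentrations, so
  `ChemicalMeta.lod_native` divides those by 1000 before they are
  compared with simulated values. Even so, several printed
  LOD/GM/%-detected triples are mutually inconsistent (e.g. PFOS: GM
  13.6 µg/L below its LOD of 14.2 µg/L yet 100% detected), so the
  generator reports *realized* censoring fractions rather than
  promising the printed ones.
* **Covariates.** Categorical covariates are drawn independently from
  the published marginal frequencies (61.7% white, 53.7% female
  infants, 11.2% active smokers, ...). Age is truncated-normal
  (29.5 ± 5.6 y on [18, 45]), BMI log-normal (median 26.2,
  log-SD 0.21, matching the published category fractions to a few
  percent), GA truncated-normal (39.0 ± 1.8 weeks on [24, 43]; the
  source never printed a GA distribution). Real demographics are
  correlated (income with insurance, smoking with education); the
  independence simplification means passing tests demonstrate the
  machinery, not robustness to realistic covariate confounding.
* **Outcome.** Per-chemical coefficients are drawn once per cohort
  from the class-level truth and returned alongside `y` for recovery
  testing. The default truth uses the published class-level point
  estimates (mu_beta = +1, −11, +0.2, −4, +7 g for
  phthalates/PFAS/PCBs/PBDEs/OCPs; sigma_beta = 10, 24, 5, 12, 18 g;
  covariate effects from the published adjusted model; residual SD
  500 g; GA curve ≈ 185 g/week near term with mild concavity, zero at
  39 weeks) — i.e. a *near-null* world, which is what the source
  cohort looked like. A `null` preset zeroes every chemical effect.

## Preprocessing

The order is fixed and load-bearing: substitute LOD/sqrt2 for censored
values → log10 → average available visits → standardize. Standardizing
uses the sample SD (n−1); the per-chemical SD of the visit-averaged
log10 value is retained for the per-10-fold back-transformation.
Participants with any missing field are dropped (complete case) and
counted. The two OPP metabolites enter separately by default (they are
conventionally reported separately) with a molar-sum option
(DEP/154.10 + DMP/126.05, g/mol) available; reference levels for the
covariate coding are white, male, ≥ high school, cotinine ≤ 3 ng/ml,
income ≥ $25k, employed, private insurance, living with partner, no
prenatal vitamins, with age and BMI continuous.

## Recovery study and its calibration

`run_recovery_study` loops simulate → fit and reports per-class bias,
RMSE, and 95%/50% CI coverage for `mu_beta` and `sigma_beta`.
Two deliberate choices:

* **Recovery truth.** Parameter-recovery simulations need effects the
  data can actually pin down; the `recovery` preset uses
  mu_beta = (+30, −40, +10, −20, +25) g/SD, sigma_beta =
  (15, 25, 8, 15, 20) g and residual SD 350 g. The near-null default
  truth would leave the bias metric dominated by Monte-Carlo noise at
  any feasible replicate count.
* **Pooled coverage.** Coverage of the class-mean intervals is
  reported per class *and* pooled over the 5 classes. At 30 replicates
  a per-class coverage estimate has granularity 1/30 and equals 1.0
  with probability ≈ 0.21 per class even for perfectly calibrated 95%
  intervals; the pooled estimate (150 interval trials) is the one a
  fixed acceptance band is applied to.

Even for the pooled bias metric, the irreducible per-replicate noise in
the class-mean estimate is about `sigma_beta/sqrt(m)` (m = class
size), because each replicate draws its own coefficients around the
class mean; at 30 replicates the bias check for a 5-member class
therefore operates at roughly a 1.8-SE margin. This is inherent to the
design (only more replicates or larger classes tighten it), and is why
the recovery metrics should be read as calibration checks, not
precision measurements.

## Problem sizes

Routine runs use n = 272 participants (the complete-case size of the
motivating cohort) with the 2 x 2,000 sampler budget; the recovery
study uses 30 replicates at n = 300; generator calibration checks use
n = 100,000. These sizes give each check comfortable resolution while
keeping a full test-suite run in the minutes range on one CPU.

## Known limitations

* Independent covariates and a single two-parameter correlation
  structure; no assay batch effects, no creatinine/lipid normalization
  arithmetic (concentrations are generated already normalized).
* No between-class coefficient covariance, interactions, or nonlinear
  exposure terms — matching the modelled analysis, which shares these
  limits.
* The catalog's printed LOD/GM/%-detected inconsistencies are carried
  as-is; inclusion by flag and inclusion by the 90% rule genuinely
  disagree, and both modes are exposed with their symmetric difference
  rather than adjudicated.
* Stratified (by infant sex) analyses re-standardize exposures within
  stratum, so per-SD estimates are not directly comparable across
  strata; the per-10-fold scale is.
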