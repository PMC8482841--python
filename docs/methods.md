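# Methods

This note documents the models implemented in `riskscape`, the
estimation and numerical choices behind them, what the synthetic cohort
generator does and does not emulate, and the known limitations.

## 1. Risk scores

**Functional-health risk score (FRS, 0–5).** Pulse pressure (systolic −
diastolic, mm Hg) is banded `<52 → 0`, `52–72 → 1`, `>72 → 2`; BMI
(kg/m²) is banded `normal [18.5, 25) → 0`, `underweight (<18.5) or
overweight [25, 30] → 1`, `obese (>30) → 2`; grip strength (kg/f) is
dichotomised at the baseline mean of the participant's APOE stratum
(`≥ mean → 0`, else 1). The published bands abut at 52/72, 25/30 and
at the stratum mean; our boundary conventions (moderate bands
upper-inclusive, "strong/high" defined as value ≥ mean) are
deterministic and documented here because no source states them. The
underweight bound is 18.5 kg/m², the WHO convention.

**Lifestyle-reserve risk score (LRS, 0–6).** Four activity-frequency
totals (physical, social, cognitive-integrative, cognitive-novel) each
dichotomised at the APOE-stratum baseline mean (high participation →
0, low → 1); education banded `>11 years → 0`, `8–11 → 1`, `<8 → 2`.

**M-CRS (0–11)** is FRS + LRS. A participant missing any component of
a score is dropped from analyses of that score (listwise on
predictors), mirroring the removal of missing predictor values in the
original workflow. Stratum-mean cutoffs are computed once on the
baseline sample stratified by APOE ε4−/ε4+ only; they are *not*
recomputed inside AD-GRS subgroups, because the cutoff definition is
anchored to the APOE stratification. The weight thresholds are
externalisable (JSON/YAML) and per-indicator weights are emitted as
audit columns.

## 2. Genetic risk

The Hardy–Weinberg check is the asymptotic df = 1 χ² comparing observed
genotype counts with n·p², 2npq, n·q² at the observed allele
frequencies, without continuity correction (this reproduces the
published CR1 statistic to three decimals); a conditional exact test
(Wigginton-style) is available as an option but is not the default.
APOE is grouped ε4− / ε4+, with ε2/ε4 heterozygotes excluded because
the two alleles carry opposing effects. The AD-GRS counts
risk-allele-carrying genotypes (dominant coding) at CLU (C+), CR1 (A+)
and PICALM (T+), giving 0–3, with a fixed low (0–1) / high (2–3) split;
the split is hard-coded rather than recomputed as a sample median, for
reproducibility.

## 3. EF measurement model

Twelve observed variables (4 tests × 3 waves) follow a multivariate
normal with structured moments: Λ (one latent EF factor per wave;
optionally inhibition + shifting factors), intercepts τ, factor means
α, factor covariance Ψ (all 3 (or 6) factors freely covarying across
waves), and residual covariance Θ that is block-diagonal by *test*:
each test's 3×3 across-wave residual block is free, the standard
longitudinal-CFA allowance for test-specific method variance.

*Identification* uses the marker convention (first loading per factor
fixed to 1; factor means fixed to 0 until intercepts are constrained,
then wave-1 means stay 0 and later means are free).

*Estimation* is casewise FIML: cases grouped by missingness pattern,
each pattern contributing the normal log-density on its observed
subset via per-pattern sufficient statistics (so cost is independent
of n given the patterns). Gradients are analytic (chain rule through
Λ, τ, α, Cholesky factors of Ψ and of the Θ blocks; log-transformed
diagonals), optimised by L-BFGS-B with a moment-based start, up to
three seeded restarts and a tightened polishing pass; convergence
requires max |gradient| < 1e−3 on the −logL scale. Residual variances
estimated at ≈0 are flagged as Heywood cases. The residual-invariance
model (equal variances, free covariances per block) cannot use a
Cholesky and instead penalises non-positive-definite trials.

*Fit indices.* Model χ² is the likelihood ratio against the
FIML-saturated model (free mean vector + covariance matrix, estimated
by EM); RMSEA = √(max(χ²−df, 0)/(df·n)); CFI uses the independence
baseline (free means and variances, zero covariances); SRMR is a FIML
analogue computed from saturated-versus-implied correlation residuals
plus standardised SD residuals (raw complete-data SRMR is undefined
under missingness). Thresholds used descriptively: RMSEA ≤ 0.05,
CFI ≥ 0.95, SRMR ≤ 0.08.

*Invariance ladder.* Configural → metric (equal loadings) → scalar
(equal intercepts, wave-2/3 factor means freed) → residual (equal
residual variances), each step a Δχ² = 2ΔlogL test at α = 0.05. If
scalar is rejected, intercepts are freed one at a time — candidates
ranked by an approximate one-parameter likelihood gain (score² / 2·
curvature), ties broken by lowest indicator index — up to two of the
twelve; if the test against metric is still significant the ladder
falls back to metric. Each constrained model is warm-started from the
previous fit.

*Factor scores.* Both regression (empirical-Bayes) and Bartlett scores
are implemented, computed casewise on each participant's observed
indicators; a wave with no observed indicator gets no score. The
pipeline default is **Bartlett**, because the scores are the *dependent
variable* of the growth stage: Bartlett scores are conditionally
unbiased (E[score | η] = η), so downstream regression coefficients are
unattenuated, whereas regression scores are shrunken and transmit that
shrinkage into the growth-stage coefficients (the Skrondal–Laake
argument for choosing score types by their role). Regression scores
remain available and are validated against their closed-form
expression.

## 4. Growth models

EF factor scores are modelled on chronological age centred at 75 years
(accelerated longitudinal design; wave index is never the time
metric): person-specific intercept and slope, bivariate-normal random
effects G, and per-wave residual variances (3 parameters; a common
residual is available). Estimation is marginal ML with fixed effects
profiled out by GLS inside the variance optimisation (L-BFGS-B on log
standard deviations / Cholesky entries). Standard errors come from the
inverse observed information (central-difference Hessian of the full
likelihood at the optimum; GLS covariance as a guarded fallback);
inference is two-sided Wald z, matching common SEM-software practice,
not t. Parameter counts: the two-predictor conditional random-slope
model has 6 regression + 3 random-effect + 3 residual = 12 free
parameters; stratified models are estimated per group and combined
(summed logL and k, information criteria on the total n — the BIC n
for multiple-group models is a documented choice, as the convention is
not fixed in the field).

The model-building ladder (null → random intercept → + fixed slope →
+ random slope → + fixed quadratic) uses Δχ² tests between consecutive
stages; variance additions lie on the parameter boundary, so those
steps carry an explicit mixture-χ² caveat flag rather than an adjusted
p-value. Tests of a constant predictor are impossible, so constant
columns are dropped with a warning and the parameter count reduced
accordingly. −2LL, AIC = −2LL + 2k and BIC = −2LL + k·ln(n) are exact
identities of the reported logL.

Moderation analyses follow the three-step design: RQ1 regresses EF
intercept and slope on each risk score (plus sex) pooled; RQ2
stratifies by APOE ε4±; RQ3 fits a separate low/high AD-GRS two-group
model inside each APOE stratum. Strata below 15 participants (the
smallest published stratum) are fitted but flagged `low_n`.

## 5. Synthetic cohort generator

The generator emulates the target design: n = 602 by default; baseline
age uniform on [53, 85] so wave-3 ages reach ≈95 (the 40-year band);
wave gaps normal with means 4.4 and 4.5 years (SD 0.5, truncated at 1);
66% women; marginal retention 0.81 (wave 2) and 0.56 (wave 3), the
latter decomposed into a third-wave *opportunity* subset (fraction
0.56/0.88) retained at 0.88 — both the raw and opportunity-adjusted
rates are thereby reproduced without asserting the original
adjustment arithmetic. Attrition is monotone; the default mechanism is
MAR with the retention logit depending on current age and the
*previous wave's observed* indicator composite (weights −0.5 and +0.5
per SD, intercept solved so the realised marginal rate matches the
target); MCAR and single-covariate MAR variants are available for
oracle tests. Missing-at-random here is genuine: the missingness model
uses only observed data.

Genotypes: APOE allele frequencies with ε2 fixed at 0.08 and the ε4
frequency solved so that the ε4-carrier fraction among non-ε2/ε4
participants matches 149/602; CLU/CR1/PICALM drawn independently under
Hardy–Weinberg at risk-allele frequencies 0.62/0.398/0.575 (the latter
two implied by the published genotype counts). Baseline indicators are
drawn per APOE stratum at the published stratum means/SDs (an optional
correlation matrix couples them; default independent), independent of
the three AD-GRS SNPs. Health-history exclusion violators
(antipsychotic medication, MMSE < 24, uncontrolled hypertension,
insulin-treated diabetes, head injury) are planted at roughly the
published rates so the exclusion filter has work to do.

The latent EF process is the growth model above with true parameters
calibrated to the published effects: risk→level −0.161 and risk→slope
−0.007 per M-CRS point (risk centred at its realised mean), sex→level
+0.275 and sex→slope +0.015 (female = 1, so positive coefficients mean
better EF in women — the documented sign convention), intercept mean 0
and slope mean −0.02/year at age 75, intercept variance 0.35, slope
variance 0.0016 (slope SD 0.04/year, intercept–slope correlation
−0.21) and wave disturbance 0.10. The slope variance is set at a
magnitude typical of latent cognitive slopes and large enough that the
foundational random-slope model is the preferred ladder stage at
n = 600, as in the study being emulated. Indicators load 1.0/0.9/0.8/
0.9 with residual variances 0.2 and cross-wave residual correlation
0.3, oriented so higher = better EF (a convention, since scoring
directions of latency/error tests are not standardised).

**What passing tests do and do not show.** The generator produces
linear-in-age latent trajectories, normal indicators, stratum-wise
homogeneous indicator distributions, and missingness that is exactly
MAR (or MCAR). Real cohort data offer none of these guarantees —
non-normal test scores, practice effects, selective mortality
(MNAR), genotype–lifestyle correlation. Recovery of planted effects
therefore validates the *estimation machinery*, not the
substantive robustness of the design to violations the generator does
not model. One known subtlety is reproduced faithfully: because
grip/activity cutoffs are sample-stratum means, re-deriving the risk
scores on a filtered or perturbed sample relabels a few participants
near the cutoff, which attenuates refitted coefficients by a few
percent relative to the realised generating score — simulate-and-refit
oracles therefore regress on the realised generating score itself.

## 6. Numerical choices and degenerate inputs

- Optimiser tolerances: measurement ftol 1e−12 (plus a 1e−16 polishing
  pass, L-BFGS memory 30), gradient criterion 1e−3; growth ftol 1e−13
  with variance parameters bounded in log space (±15) to keep marginal
  covariances regular. Numerical Hessian steps are 1e−4·max(1, |θ|).
- Non-positive-definite trial covariances are penalised (objective
  1e12), never clamped; degenerate requested evaluations (zero
  variances with data on the mean line) raise rather than return a
  divergent likelihood.
- Monomorphic SNPs make the HWE statistic undefined and raise.
- Single-wave data leave slope stages unidentified and raise an
  explicit identifiability error.
- Cohorts are validated on construction: unique ids, strictly
  increasing observed ages (violations name the row), finite observed
  EF values; CSV round-trips preserve full float precision.

## 7. Problem sizes used by the test and acceptance runs

Monte-Carlo checks use n = 600 cohorts with 100 replicates for
parameter recovery (mean estimates checked against their own
Monte-Carlo 95% interval), 400 permutation replicates for type-I
calibration, 100 seeds for the invariance and growth-ladder detection
rates, and 30 seeds for planted-violation recovery. These sizes give
Monte-Carlo standard errors comfortably inside the asserted bounds
while keeping a full run in the minutes range on one CPU.

## 8. Known limitations

- Two-stage estimation (factor scores, then growth) is deliberate,
  matching the emulated workflow; a single-stage full-SEM growth model
  is out of scope.
- No robust (sandwich / Satorra–Bentler) corrections, no categorical-
  indicator estimation, no quadratic random effects, no multiple-
  testing correction across moderation cells (none was applied in the
  emulated analysis).
- Wald z inference is first-order; boundary variance tests are flagged
  but not mixture-corrected.
- The AD-GRS is the fixed 3-SNP carrier score; no dosage coding,
  imputation, or linkage-disequilibrium modelling.
- The generator draws genotypes independent of lifestyle and health
  indicators; gene–environment correlation can be introduced only
  through the configurable indicator correlation matrix.
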