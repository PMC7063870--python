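# Methods

## The causal question and the estimator

`uricmr` estimates the causal effect of serum uric acid on incident
metabolic syndrome (MetS) and its four components in a one-sample
Mendelian randomization (MR) design. A single SNP in the urate
transporter gene *SLC2A9* (rs11722228, effect allele T, additive coding
0/1/2) serves as the instrument. Writing

- β₁ — per-allele effect of the SNP on age-standardized serum uric acid
  (SD units, ordinary linear model),
- β₂ — per-allele log hazard ratio of the SNP on the outcome (Cox
  proportional-hazards model),

the Wald-ratio causal log hazard ratio per SD of uric acid is

    β₃ = β₂ / β₁,     S₃ = S₂ / |β₁|,

with the first-order delta-method SE treating β₁ as fixed, and the
reported causal hazard ratio exp(β₃) with 95% interval
exp(β₃ ± 1.96·S₃). The identifying assumptions are the usual
instrumental-variable ones: the SNP is associated with the exposure,
shares no common cause with the outcome, and affects the outcome only
through uric acid (no pleiotropy). Multi-SNP estimators (IVW, MR-Egger,
weighted median) are out of scope for this single-instrument design.

Ignoring the sampling error of β₁ understates S₃ when the instrument is
weak. `mr_delta_vs_montecarlo` quantifies the gap by simulating the
ratio's sampling distribution from independent normals at the point
estimates; at the realistic instrument strength here (first-stage
F ≈ 28) the Monte-Carlo SD agrees with S₃ within 15%, while a weak
instrument (β₁ near 0) makes the ratio heavy-tailed and the delta SE an
understatement, which the diagnostic flags. The first-stage F statistic
is reported with every MR result but never used as a gate.

Applied to the published per-allele estimates for the MetS cohort
(β₁ = 0.23, outcome HR 0.92 with 95% CI 0.62–1.38, from which
S₂ = (ln 1.38 − ln 0.62)/3.92 = 0.2041), the chain reproduces the
published causal HR 0.70 and lower bound 0.12. The upper bound
reconstructs to 3.96 from these rounded inputs, whereas the publication
prints 4.12; the discrepancy is an input-rounding gap (the original
authors evidently carried more digits in β₂/S₂) and is documented here
rather than asserted in tests.

## Phenotyping and cohort construction

Components follow the Chinese Diabetes Society 2004 criteria:
overweight/obesity BMI ≥ 25 kg/m²; hyperglycemia FPG ≥ 6.1 mmol/L or
post-load glucose ≥ 7.8 mmol/L (when measured) or glucose-lowering
treatment; hypertension SBP ≥ 140 or DBP ≥ 90 mmHg or antihypertensive
treatment; dyslipidemia TG ≥ 1.7 mmol/L or HDL-c < 1.0 (women) /
< 0.9 (men) mmol/L. MetS is three or more components. Conventions the
source description leaves open, fixed here:

- "Previously diagnosed and treated" is operationalized by the drug-use
  flags alone; no separate diagnosis field is required.
- Missing post-load glucose is non-contributory (check-up cohorts rarely
  measure it); FPG and the treatment clause suffice.
- Onset between visits is assigned to the right interval endpoint: the
  event time is the first visit at which the criteria are met. No
  interval-censored likelihood is used.
- Cardio-/cerebrovascular exclusion at baseline uses an optional
  self-report `cvd` column, since no laboratory criterion exists.
- A component flag is monotone in the risk direction of each lab (HDL-c
  is protective, so monotone in −HDL); this is the property the tests
  check.

Cohorts keep subjects with ≥ 2 visits and baseline age > 20, exclude
prevalent MetS/CVD at baseline, and for each component subcohort
additionally exclude subjects with that component at baseline.
Person-years are summed from baseline to event or last visit; incidence
density is events per 1000 person-years.

Serum uric acid is z-standardized within 5-year age bands [20,25), …,
[75,80), with ages ≥ 80 pooled in one top band, using the sample SD
(divisor n−1). A band with fewer than two members or zero spread is
merged into the nearest populated band with a warning (configurable to
an error). Standardization is idempotent and invariant to affine
rescaling of the raw exposure within a band.

## Statistical estimators

- **Hardy–Weinberg test.** Pearson χ² with 1 df on the 0/1/2 genotype
  counts against expectations from the estimated allele frequency, no
  continuity correction. Monomorphic input is an error.
- **Linear and logistic fits** delegate to statsmodels (OLS, Logit).
  Logistic separation is flagged (`converged=False`) from a bounded
  quasi-Newton refit instead of raising.
- **Cox proportional hazards** is implemented in-package: Newton–Raphson
  from β = 0 with step-halving, Efron tie correction (Breslow
  selectable), convergence when max |score| < 1e-8 or the log-likelihood
  changes by < 1e-10, model-based SEs from the observed information, and
  covariates centred for numerical stability (this changes neither β nor
  its SE). A monotone partial likelihood (all events at one covariate
  extreme) is detected by a diverging estimate (|β| > 15) and flagged
  non-converged. The implementation matches `lifelines` to ≈ 1e-6 on
  tied data and brute-force grid maximization of the explicit partial
  likelihood to 1e-4 in the test suite.
- All 95% intervals use the fixed multiplier 1.96; no multiple-testing
  adjustment is applied anywhere, matching the source analysis. Missing
  genotype or covariates are handled by complete-case deletion with a
  logged count.

The adjusted observational Cox model controls for baseline age, the
baseline indicators of the three components other than the target
outcome, and the three drug flags. Smoking and drinking are excluded
from the default adjustment set (their prevalence in this female cohort
is far too low to act as confounders) but can be added through the
analysis configuration. β₁ is estimated unadjusted, and re-estimated
within each subcohort; each MR result records the β₁ it used.

## The synthetic cohort generator

No public version of the source cohort exists, so the generator creates
cohorts with the same statistical structure, making every pipeline stage
testable. Structural model per subject:

    z  = b_G (dose − 2p) + b_U·U + ε,   Var(z) = 1
    UA = 257.33 + 52.80·z                        (µmol/L)
    hazard_k(t) = h0_k · exp(γ_X z + γ_U U)      (each outcome k)

with doses in Hardy–Weinberg proportions at p = 0.40, U a standard
normal unmeasured confounder with correlation 0.3 with age, ages
truncated-normal (mean 39.48, SD 12.05, range 21–81, all female), and
exponential event times (Weibull shape configurable). Defaults are the
emulated study conditions: n = 1381, b_G = 0.23 SD per allele,
b_U = 0.6, γ_U = 0.7 and γ_X = 0 — a *null* causal effect whose
confounding drives the naive observational hazard ratio per SD of
exposure to ≈ 1.5 while a valid instrument leaves the Wald ratio centred
on HR = 1. The effect-allele frequency is not published; 0.40 gives
instrument strength comparable to the published β₁ interval width.
h0 for MetS (0.0155/year) is set so the observed incidence density falls
in 15–25 per 1000 person-years; component baseline hazards are scaled to
the relative event counts of the component subcohorts.

Longitudinal tables place visits roughly annually (Gaussian jitter,
SD 0.15 y) over a per-subject follow-up drawn uniform on 1.5–3.5 years,
which lands the median follow-up near 2 years. Laboratory values at
each visit are drawn on the side of each diagnostic threshold dictated
by the subject's active flags (e.g. the visit at which hypertension
becomes active receives SBP ≥ 140 mmHg), so every generated record
phenotypes cleanly. Because MetS is *derived* from components by the
phenotyping rule but *simulated* as its own proportional-hazards time,
the component onset times are reconciled per subject: at most two
components may be active strictly before the subject's MetS time and at
least three are forced active from it. This slightly distorts the
component processes whenever three components would naturally co-occur
before the MetS time (rare at the default rates). Drug use (baseline
probabilities 1.0/3.4/1.1% for glucose/BP/lipid drugs) trips the
corresponding component from baseline while leaving labs unremarkable.

What the generator does **not** emulate: linkage disequilibrium or
multiple variants, pleiotropic instrument paths, measurement error in
labs, within-subject lab autocorrelation beyond the latent flags, or
the unknown real confounding structure (U is a single composite).
Passing tests therefore demonstrate correctness of the estimators and
pipeline under a proportional-hazards data-generating process, not
fidelity to any real population.

## Calibration targets versus reproducible quantities

The source cohort is private, so its data-dependent results — the
unadjusted observational HR 1.65 and adjusted HR 1.36 for MetS, the
cohort's fitted β₁ = 0.23, and the incidence density of 19.96 per 1000
person-years — are **not reproducible** by this package. They serve
only as calibration ranges for the simulator defaults above, and any
resemblance of simulated estimates to them is by construction of those
defaults. The quantities the package does reproduce exactly are the
desk-computable ones: the Wald-ratio causal HR and interval from the
published per-allele estimates.

## Replication-study problem sizes

The packaged replication checks use 200 cohorts of n = 5000 for causal
recovery (mean Wald ratio within 0.05 of a true γ_X = 0.5), 500 cohorts
of n = 1381 for null coverage under confounding (the 95% MR interval
covers HR = 1 in 92–98% of replicates while the naive observational HR
exceeds 1 in essentially all), and 2000 replicates for the HWE test's
type-I error. These sizes give Monte-Carlo standard errors comfortably
inside the asserted bands while keeping the default test run short.

## Known limitations

- Right-endpoint event-time imputation overestimates onset times by up
  to one inter-visit gap; with annual visits and these hazards the
  effect on log HRs is second-order.
- The delta-method SE ignores first-stage sampling error; with weak
  instruments the reported MR intervals are anti-conservative (the
  Monte-Carlo diagnostic exists precisely to surface this).
- The Cox fit offers no time-varying covariates, stratification,
  frailty, robust SEs, or proportionality diagnostics.
- The male HDL-c branch of the phenotyper is implemented but untested
  against any male cohort; the emulated study is all-female.
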