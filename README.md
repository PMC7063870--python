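# uricmr

One-sample, single-SNP Mendelian randomization of serum uric acid on
incident metabolic syndrome (MetS) and its components, for longitudinal
health check-up cohorts.

Observational cohort studies repeatedly find elevated serum uric acid
associated with MetS, but confounding and reverse causation make the
association a poor guide to whether urate-lowering therapy could prevent
MetS. Mendelian randomization sidesteps both by using a genetic variant —
here rs11722228 in the urate transporter gene *SLC2A9*, coded additively
as 0/1/2 effect alleles — as an instrument for uric acid: alleles are
allocated at conception, so the SNP-outcome association is free of the
usual confounding. `uricmr` implements the full analysis for
epidemiologists working with check-up data: phenotyping, incident-cohort
construction, the association models, the causal estimator, and a
synthetic-cohort generator with known truth so every stage is testable.

## The estimator

With β₁ the per-allele effect of the SNP on uric acid (z-standardized
within 5-year age bands, so β₁ is in SD units) and β₂ the per-allele log
hazard ratio of the SNP on the outcome from a Cox model, the causal log
hazard ratio per SD of uric acid is the Wald ratio

```
β₃ = β₂ / β₁,    S₃ = S₂ / |β₁|   (delta method, β₁ treated as fixed),
HR = exp(β₃),    95% CI = exp(β₃ ± 1.96·S₃).
```

The package supplies everything the ratio consumes: a Pearson χ²
Hardy–Weinberg check of the genotypes, the linear SNP→exposure fit, a
self-contained Cox proportional-hazards estimator (Newton–Raphson on the
partial likelihood, Efron tie correction), unadjusted and adjusted
observational Cox models for comparison, and a Monte-Carlo diagnostic of
the delta-method SE. See `docs/methods.md` for the model, assumptions,
and all numerical conventions.

## Worked example

The headline computation takes only the two published per-allele
estimates for the MetS cohort (n = 1381): the SNP shifts standardized
uric acid by 0.23 SD per allele (95% CI 0.14–0.31), and the SNP-MetS
hazard ratio is 0.92 (95% CI 0.62–1.38).

```python
import numpy as np
from uricmr import EffectEstimate, se_from_ci, wald_ratio

beta1 = EffectEstimate(term="geno_dose", beta=0.23,
                       se=se_from_ci(0.14, 0.31, scale="linear"),
                       scale="linear", n=1381)
beta2 = EffectEstimate(term="geno_dose", beta=np.log(0.92),
                       se=se_from_ci(0.62, 1.38, scale="log"),
                       scale="log_hazard", n=1381, events=61)
mr = wald_ratio(beta1, beta2, outcome_name="mets")
print(f"causal HR per SD uric acid: {mr.hr:.2f} "
      f"(95% CI {mr.ci_low:.2f}-{mr.ci_high:.2f}), first-stage F = {mr.first_stage_f:.1f}")
```

prints

```
causal HR per SD uric acid: 0.70 (95% CI 0.12-3.96), first-stage F = 28.1
```

i.e. no evidence of a causal effect of uric acid on MetS: the point
estimate is even protective, but the single-instrument interval is wide
(0.12–3.96). The first-stage F of 28 indicates a usably strong
instrument.

The full pipeline runs from the command line. On a synthetic cohort
generated under the default study conditions (1381 women, null causal
effect, confounding inflating the observational association):

```
$ uricmr simulate --out demo --seed 1
wrote demo/cohort.csv (1381 subjects, 4108 visits)
$ uricmr run --cohort demo/cohort.csv --out demo_out
wrote demo_out/report.json and demo_out/forest.tsv
```

`forest.tsv` holds 15 rows (5 outcomes × 3 models); the MetS rows of
this run read

```
outcome                  model       hr   ci_low  ci_high
   mets          observational 1.129132 0.805148 1.583484
   mets observational_adjusted 1.052991 0.745346 1.487617
   mets                     iv 0.460941 0.065168 3.260319
```

— the observational estimates drift above 1 under confounding while the
instrumental-variable interval comfortably covers HR = 1, the generating
truth.

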