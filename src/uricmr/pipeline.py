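"""End-to-end analysis: from a longitudinal visit table to MR estimates.

For each outcome (metabolic syndrome and its four components) the
pipeline builds the incident cohort, standardizes the exposure within
5-year age bands, fits the instrument-exposure linear model (beta1), the
instrument-outcome Cox model (beta2), the unadjusted and adjusted
observational exposure-outcome Cox models, and combines beta1 and beta2
into the Wald-ratio causal estimate.  The result serializes to JSON and
to a flat forest-plot table (outcome x {observational, adjusted, IV}).
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cohort as _cohort
from .cohort import OUTCOMES, COMPONENTS, build_cohort, standardize_exposure
from .models import EffectEstimate, HWEResult, cox_fit, hwe_test, linear_fit
from .mr import MRResult, wald_ratio

__all__ = ["AnalysisConfig", "OutcomeResult", "AnalysisReport", "run_analysis", "export_forest"]

log = logging.getLogger("uricmr")

#: Fixed row order of the forest export.
FOREST_MODELS = ["observational", "observational_adjusted", "iv"]


@dataclass
class AnalysisConfig:
    """Options of the analysis pipeline.

    The adjusted observational model controls for age, the baseline
    indicators of the components other than the target outcome, and the
    three drug flags; smoking and drinking are excluded by default (their
    prevalence in the emulated cohort is too low to matter) but can be
    added via ``extra_adjustment``.
    """

    outcomes: list = field(default_factory=lambda: list(OUTCOMES))
    adjust_drugs: bool = True
    extra_adjustment: list = field(default_factory=list)
    ties: str = "efron"
    weak_instrument_floor: float = 1e-6
    age_band_width: float = 5.0

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class OutcomeResult:
    """Every estimate the pipeline produces for one outcome."""

    outcome: str
    n: int = 0
    events: int = 0
    person_years: float = 0.0
    incidence_density: float = float("nan")
    exclusions: dict = field(default_factory=dict)
    dropped_missing_dose: int = 0
    dropped_covariates: list = field(default_factory=list)
    beta1: EffectEstimate | None = None        # SNP -> standardized exposure
    beta2: EffectEstimate | None = None        # SNP -> outcome (log HR)
    observational: EffectEstimate | None = None
    observational_adjusted: EffectEstimate | None = None
    mr: MRResult | None = None
    error: str | None = None

    def to_dict(self) -> dict:
        def conv(v):
            return v.to_dict() if v is not None else None

        return {
            "outcome": self.outcome,
            "n": self.n,
            "events": self.events,
            "person_years": self.person_years,
            "incidence_density": self.incidence_density,
            "exclusions": self.exclusions,
            "dropped_missing_dose": self.dropped_missing_dose,
            "dropped_covariates": self.dropped_covariates,
            "beta1": conv(self.beta1),
            "beta2": conv(self.beta2),
            "observational": conv(self.observational),
            "observational_adjusted": conv(self.observational_adjusted),
            "mr": conv(self.mr),
            "error": self.error,
        }


@dataclass
class AnalysisReport:
    """Per-outcome estimate bundle plus sample-wide diagnostics."""

    hwe: HWEResult
    outcomes: dict  # name -> OutcomeResult
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "hwe": self.hwe.to_dict(),
            "outcomes": {k: v.to_dict() for k, v in self.outcomes.items()},
            "provenance": self.provenance,
        }

    def to_json(self, path=None, with_timestamp: bool = True) -> str:
        payload = self.to_dict()
        if not with_timestamp:
            payload["provenance"] = {
                k: v for k, v in payload["provenance"].items() if k != "timestamp"
            }
        text = json.dumps(payload, indent=2, default=_cohort._json_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _baseline_table(df: pd.DataFrame) -> pd.DataFrame:
    df = df.sort_values(["subject_id", "visit_time"], kind="mergesort")
    return df.groupby("subject_id", sort=False).head(1)


def run_analysis(df: pd.DataFrame, config: AnalysisConfig | None = None) -> AnalysisReport:
    """Run the full observational + Mendelian randomization analysis.

    ``df`` is a longitudinal visit table in the documented schema.  A
    failure in one outcome is recorded in that outcome's ``error`` field
    and the pipeline continues with the rest.
    """
    config = config or AnalysisConfig()

    baseline = _baseline_table(df)
    doses = baseline["geno_dose"].dropna().astype(int)
    counts = doses.value_counts()
    hwe = hwe_test(int(counts.get(0, 0)), int(counts.get(1, 0)), int(counts.get(2, 0)))

    results = {}
    for outcome in config.outcomes:
        res = OutcomeResult(outcome=outcome)
        results[outcome] = res
        try:
            ac = build_cohort(df, outcome)
            data = ac.data
            n_missing = int(data["geno_dose"].isna().sum())
            if n_missing:
                log.info("%s: dropping %d subjects with missing genotype", outcome, n_missing)
                data = data[data["geno_dose"].notna()]
            res.exclusions = ac.exclusions
            res.dropped_missing_dose = n_missing
            res.n = len(data)
            res.events = int(data["event"].sum())
            res.person_years = float(data["time"].sum())
            res.incidence_density = _cohort.incidence_density(res.events, res.person_years)

            dose = data["geno_dose"].to_numpy(dtype=float)
            z = standardize_exposure(
                data["uric_acid"].to_numpy(dtype=float),
                data["age"].to_numpy(dtype=float),
                band_width=config.age_band_width,
            )
            time = data["time"].to_numpy(dtype=float)
            event = data["event"].to_numpy(dtype=int)

            res.beta1 = linear_fit(z, dose, term="geno_dose")
            res.beta2 = cox_fit(time, event, dose, ties=config.ties, term="geno_dose")
            res.observational = cox_fit(time, event, z, ties=config.ties, term="uric_acid_sd")

            adj_cols = ["age"]
            adj_cols += [f"baseline_{c}" for c in COMPONENTS if c != outcome]
            if config.adjust_drugs:
                adj_cols += ["drug_glucose", "drug_bp", "drug_lipid"]
            adj_cols += list(config.extra_adjustment)
            covs = data[adj_cols].astype(float)
            constant = [c for c in covs.columns if covs[c].nunique() <= 1]
            if constant:
                log.info("%s: dropping constant covariates %s", outcome, constant)
                covs = covs.drop(columns=constant)
            res.dropped_covariates = constant
            res.observational_adjusted = cox_fit(
                time, event, z, covariates=covs, ties=config.ties, term="uric_acid_sd"
            )

            res.mr = wald_ratio(
                res.beta1, res.beta2,
                outcome_name=outcome,
                weak_floor=config.weak_instrument_floor,
            )
        except Exception as exc:  # record and continue with remaining outcomes
            log.warning("%s: analysis failed: %s", outcome, exc)
            res.error = str(exc)

    provenance = {
        "n_input_rows": int(len(df)),
        "n_subjects": int(baseline.shape[0]),
        "config": dataclasses.asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
        ).hexdigest()[:12],
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return AnalysisReport(hwe=hwe, outcomes=results, provenance=provenance)


def export_forest(report: AnalysisReport, path=None) -> pd.DataFrame:
    """Flat forest-plot table: (outcome, model, hr, ci_low, ci_high).

    Rows appear in fixed order: each outcome with its observational,
    adjusted-observational and IV hazard ratios.  At export time the IV
    row is checked to equal the Wald ratio recomputed from the report's
    own beta1/beta2 entries; incomplete outcomes export partially with a
    warning.
    """
    import warnings

    rows = []
    for outcome, res in report.outcomes.items():
        est = {
            "observational": res.observational,
            "observational_adjusted": res.observational_adjusted,
        }
        for model in FOREST_MODELS[:2]:
            e = est[model]
            if e is None:
                warnings.warn(f"{outcome}: missing {model} estimate; skipping row", stacklevel=2)
                continue
            rows.append({
                "outcome": outcome, "model": model,
                "hr": float(np.exp(e.beta)), "ci_low": e.ci_low, "ci_high": e.ci_high,
            })
        if res.mr is None:
            warnings.warn(f"{outcome}: missing IV estimate; skipping row", stacklevel=2)
            continue
        check = wald_ratio(res.beta1, res.beta2)
        if not np.isclose(check.hr, res.mr.hr, rtol=0, atol=1e-12):
            raise AssertionError(f"{outcome}: IV estimate inconsistent with its beta1/beta2")
        rows.append({
            "outcome": outcome, "model": "iv",
            "hr": res.mr.hr, "ci_low": res.mr.ci_low, "ci_high": res.mr.ci_high,
        })
    table = pd.DataFrame(rows, columns=["outcome", "model", "hr", "ci_low", "ci_high"])
    if path is not None:
        table.to_csv(path, sep="\t", index=False)  # shortest round-trip float repr
    return table
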