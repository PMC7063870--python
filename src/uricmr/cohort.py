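"""Cohort data model, phenotyping, and cohort construction.

Longitudinal health check-up data are held in a pandas DataFrame with one
row per subject-visit (see :data:`REQUIRED_COLUMNS`).  This module defines

* metabolic-syndrome phenotyping under the Chinese Diabetes Society 2004
  criteria (three or more of overweight/obesity, hyperglycemia,
  hypertension, dyslipidemia);
* construction of incident-outcome analysis cohorts (baseline exclusion of
  prevalent cases, first-crossing event times, administrative censoring);
* age-band z-standardization of the exposure (serum uric acid);
* CSV input/output with schema validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "OUTCOMES",
    "PhenotypeError",
    "SchemaError",
    "PhenotypeFlags",
    "AnalysisCohort",
    "phenotype",
    "phenotype_frame",
    "build_cohort",
    "standardize_exposure",
    "incidence_density",
    "read_cohort_csv",
    "write_cohort_csv",
    "write_results",
]

#: Mandatory per-visit columns of a longitudinal cohort table.
REQUIRED_COLUMNS = [
    "subject_id",
    "visit_time",   # decimal years relative to an arbitrary epoch
    "age",          # years at the visit
    "sex",          # "female" / "male"
    "bmi",          # kg/m^2
    "fpg",          # fasting plasma glucose, mmol/L
    "sbp",          # mmHg
    "dbp",          # mmHg
    "tg",           # triglycerides, mmol/L
    "hdl",          # HDL cholesterol, mmol/L
    "ldl",          # LDL cholesterol, mmol/L
    "uric_acid",    # serum uric acid, umol/L
    "smoker",
    "drinker",
    "drug_glucose",
    "drug_bp",
    "drug_lipid",
    "geno_dose",    # 0/1/2 copies of the effect allele, NA allowed
]

#: Recognised optional columns.
OPTIONAL_COLUMNS = ["pg2h", "cvd"]

#: The five incident outcomes the pipeline analyses.
OUTCOMES = [
    "mets",
    "overweight_obesity",
    "hyperglycemia",
    "hypertension",
    "dyslipidemia",
]

COMPONENTS = OUTCOMES[1:]

# Diagnostic thresholds (Chinese Diabetes Society 2004)
BMI_CUT = 25.0       # kg/m^2
FPG_CUT = 6.1        # mmol/L
PG2H_CUT = 7.8       # mmol/L (post-load glucose, when measured)
SBP_CUT = 140.0      # mmHg
DBP_CUT = 90.0       # mmHg
TG_CUT = 1.7         # mmol/L
HDL_CUT_FEMALE = 1.0  # mmol/L
HDL_CUT_MALE = 0.9    # mmol/L


class PhenotypeError(ValueError):
    """A check-up record is missing a field required for phenotyping."""


class SchemaError(ValueError):
    """A cohort table does not conform to the documented schema."""


@dataclass(frozen=True)
class PhenotypeFlags:
    """Component diagnoses for one check-up record."""

    overweight_obesity: bool
    hyperglycemia: bool
    hypertension: bool
    dyslipidemia: bool

    @property
    def n_components(self) -> int:
        return (
            int(self.overweight_obesity)
            + int(self.hyperglycemia)
            + int(self.hypertension)
            + int(self.dyslipidemia)
        )

    @property
    def mets(self) -> bool:
        """Metabolic syndrome: three or more component disturbances."""
        return self.n_components >= 3


def phenotype(record) -> PhenotypeFlags:
    """Phenotype a single check-up record.

    Parameters
    ----------
    record : mapping
        Anything dict-like (a ``pandas.Series`` row, a dict) carrying the
        measurement fields of :data:`REQUIRED_COLUMNS`.  ``pg2h`` is
        optional; when missing it does not contribute to hyperglycemia.

    Raises
    ------
    PhenotypeError
        If a required measurement or drug flag is absent/NaN, naming it.
    """
    required = ["bmi", "fpg", "sbp", "dbp", "tg", "hdl",
                "drug_glucose", "drug_bp", "drug_lipid", "sex"]
    for name in required:
        try:
            value = record[name]
        except (KeyError, IndexError):
            raise PhenotypeError(f"missing required field: {name}") from None
        if value is None or (isinstance(value, float) and np.isnan(value)):
            raise PhenotypeError(f"missing required field: {name}")

    pg2h = record.get("pg2h") if hasattr(record, "get") else record["pg2h"] if "pg2h" in record else None
    has_pg2h = pg2h is not None and not (isinstance(pg2h, float) and np.isnan(pg2h))

    overweight = record["bmi"] >= BMI_CUT
    hyperglycemia = (
        record["fpg"] >= FPG_CUT
        or (has_pg2h and pg2h >= PG2H_CUT)
        or bool(record["drug_glucose"])
    )
    hypertension = (
        record["sbp"] >= SBP_CUT
        or record["dbp"] >= DBP_CUT
        or bool(record["drug_bp"])
    )
    hdl_cut = HDL_CUT_MALE if record["sex"] == "male" else HDL_CUT_FEMALE
    dyslipidemia = record["tg"] >= TG_CUT or record["hdl"] < hdl_cut

    return PhenotypeFlags(
        overweight_obesity=bool(overweight),
        hyperglycemia=bool(hyperglycemia),
        hypertension=bool(hypertension),
        dyslipidemia=bool(dyslipidemia),
    )


def phenotype_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorized phenotyping of a whole visit table.

    Returns a DataFrame aligned with ``df`` carrying boolean columns for the
    four components plus ``mets`` and the integer ``n_components``.  Missing
    required measurements raise :class:`PhenotypeError` naming the field.
    """
    for name in ["bmi", "fpg", "sbp", "dbp", "tg", "hdl",
                 "drug_glucose", "drug_bp", "drug_lipid", "sex"]:
        if name not in df.columns:
            raise PhenotypeError(f"missing required field: {name}")
        if name != "sex" and df[name].isna().any():
            raise PhenotypeError(f"missing required field: {name}")

    pg2h = df["pg2h"] if "pg2h" in df.columns else pd.Series(np.nan, index=df.index)
    hdl_cut = np.where(df["sex"].to_numpy() == "male", HDL_CUT_MALE, HDL_CUT_FEMALE)

    out = pd.DataFrame(index=df.index)
    out["overweight_obesity"] = df["bmi"].to_numpy() >= BMI_CUT
    out["hyperglycemia"] = (
        (df["fpg"].to_numpy() >= FPG_CUT)
        | (pg2h.to_numpy() >= PG2H_CUT)  # NaN compares False
        | (df["drug_glucose"].to_numpy().astype(bool))
    )
    out["hypertension"] = (
        (df["sbp"].to_numpy() >= SBP_CUT)
        | (df["dbp"].to_numpy() >= DBP_CUT)
        | (df["drug_bp"].to_numpy().astype(bool))
    )
    out["dyslipidemia"] = (df["tg"].to_numpy() >= TG_CUT) | (df["hdl"].to_numpy() < hdl_cut)
    out["n_components"] = out[COMPONENTS].sum(axis=1).astype(int)
    out["mets"] = out["n_components"] >= 3
    return out


@dataclass
class AnalysisCohort:
    """Analysis-ready incident cohort for one target outcome.

    ``data`` has one row per retained subject with baseline covariates,
    genotype dose, and the survival outcome (``time`` in years from
    baseline, ``event`` 0/1).  ``exclusions`` records why subjects were
    dropped.
    """

    outcome: str
    data: pd.DataFrame
    exclusions: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def events(self) -> int:
        return int(self.data["event"].sum())

    @property
    def person_years(self) -> float:
        return float(self.data["time"].sum())

    @property
    def incidence_density(self) -> float:
        return incidence_density(self.events, self.person_years)


def build_cohort(df: pd.DataFrame, target_outcome: str) -> AnalysisCohort:
    """Build the incident analysis cohort for ``target_outcome``.

    Rules: baseline is each subject's first visit; subjects with fewer than
    two visits, age <= 20 at baseline, prevalent metabolic syndrome or
    cardiovascular/cerebrovascular disease (optional ``cvd`` flag) at
    baseline, or (for component outcomes) the target component at baseline
    are excluded.  The event time is the time of the first visit at which
    phenotyping flags the target (onset between visits is assigned to the
    right interval endpoint); non-events are censored at the last visit.

    Raises
    ------
    ValueError
        If visit times are not strictly increasing within a subject, or the
        outcome name is unknown.
    """
    if target_outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome: {target_outcome!r}; expected one of {OUTCOMES}")

    df = df.sort_values(["subject_id", "visit_time"], kind="mergesort").reset_index(drop=True)
    diffs = df.groupby("subject_id")["visit_time"].diff()
    if (diffs.dropna() <= 0).any():
        bad = df.loc[diffs <= 0, "subject_id"].iloc[0]
        raise ValueError(f"non-increasing visit times for subject {bad!r}")

    flags = phenotype_frame(df)
    work = pd.concat([df, flags.add_prefix("flag_")], axis=1)

    exclusions = {"lt2_records": 0, "age_le_20": 0, "baseline_prevalent": 0}
    rows = []
    for sid, g in work.groupby("subject_id", sort=False):
        if len(g) < 2:
            exclusions["lt2_records"] += 1
            continue
        base = g.iloc[0]
        if base["age"] <= 20:
            exclusions["age_le_20"] += 1
            continue
        cvd = base.get("cvd", 0)
        if cvd is None or (isinstance(cvd, float) and np.isnan(cvd)):
            cvd = 0
        prevalent = bool(base["flag_mets"]) or bool(cvd)
        if target_outcome != "mets":
            prevalent = prevalent or bool(base[f"flag_{target_outcome}"])
        if prevalent:
            exclusions["baseline_prevalent"] += 1
            continue

        follow = g.iloc[1:]
        hits = follow[follow[f"flag_{target_outcome}"]]
        if len(hits):
            time = float(hits.iloc[0]["visit_time"] - base["visit_time"])
            event = 1
        else:
            time = float(g.iloc[-1]["visit_time"] - base["visit_time"])
            event = 0

        row = {
            "subject_id": sid,
            "age": base["age"],
            "sex": base["sex"],
            "uric_acid": base["uric_acid"],
            "geno_dose": base["geno_dose"],
            "smoker": base["smoker"],
            "drinker": base["drinker"],
            "drug_glucose": base["drug_glucose"],
            "drug_bp": base["drug_bp"],
            "drug_lipid": base["drug_lipid"],
            "time": time,
            "event": event,
        }
        for comp in COMPONENTS:
            row[f"baseline_{comp}"] = bool(base[f"flag_{comp}"])
        rows.append(row)

    data = pd.DataFrame(rows)
    return AnalysisCohort(outcome=target_outcome, data=data, exclusions=exclusions)


def standardize_exposure(
    values,
    ages,
    band_width: float = 5.0,
    band_start: float = 20.0,
    band_top: float = 80.0,
    policy: str = "merge",
) -> np.ndarray:
    """Z-standardize an exposure within closed-open age bands.

    Bands are ``[20,25), [25,30), ..., [75,80)`` with everyone aged
    ``band_top`` or older pooled into a single top band.  Within each band
    ``z = (x - mean)/sd`` using the sample SD (divisor ``n-1``), so each
    band has mean 0 and SD 1.

    A band with fewer than two members or zero spread is, under the default
    ``policy="merge"``, merged into the nearest populated band (by band
    center) with a warning; ``policy="error"`` raises instead.
    """
    x = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if x.shape != a.shape:
        raise ValueError("values and ages must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 subjects to standardize")

    idx = np.floor((np.minimum(a, band_top) - band_start) / band_width).astype(int)
    idx = np.clip(idx, 0, None)

    def invalid(band_members):
        return band_members.size < 2 or np.std(x[band_members], ddof=1) == 0

    # iteratively merge degenerate bands into their nearest neighbour
    while True:
        labels = np.unique(idx)
        bad = [b for b in labels if invalid(np.flatnonzero(idx == b))]
        if not bad:
            break
        if len(bad) == len(labels):
            raise ValueError("exposure has zero spread overall; cannot standardize")
        if policy == "error":
            raise ValueError(f"degenerate age band {bad[0]} (fewer than 2 members or zero spread)")
        b = bad[0]
        good = [g for g in labels if g not in bad]
        nearest = min(good, key=lambda g: abs(g - b))
        warnings.warn(
            f"age band {b} degenerate; merging into band {nearest}",
            stacklevel=2,
        )
        idx[idx == b] = nearest

    z = np.empty_like(x)
    for b in np.unique(idx):
        members = np.flatnonzero(idx == b)
        mu = x[members].mean()
        sd = np.std(x[members], ddof=1)
        z[members] = (x[members] - mu) / sd
    return z


def incidence_density(events: int, person_years: float) -> float:
    """Incident events per 1000 person-years."""
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    return 1000.0 * events / person_years


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a longitudinal cohort CSV, validating the documented schema.

    Empty strings and ``NA`` are parsed as missing.  Missing mandatory
    columns raise :class:`SchemaError` naming them; unknown columns warn.
    ISO dates in ``visit_time`` are converted to decimal years using
    365.25 days/year.
    """
    df = pd.read_csv(path, na_values=["", "NA"], keep_default_na=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {', '.join(missing)}")
    unknown = [c for c in df.columns if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown columns: {', '.join(unknown)}", stacklevel=2)

    if not pd.api.types.is_numeric_dtype(df["visit_time"]):
        ts = pd.to_datetime(df["visit_time"], format="ISO8601")
        df["visit_time"] = (ts - ts.min()).dt.days / 365.25
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a longitudinal cohort table in the documented CSV schema."""
    cols = [c for c in REQUIRED_COLUMNS if c in df.columns]
    cols += [c for c in OPTIONAL_COLUMNS if c in df.columns]
    df.to_csv(path, columns=cols, index=False)


def write_results(obj, path) -> None:
    """Serialize an analysis result (any JSON-representable object) to disk."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(value):
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.bool_,)):
        return bool(value)
    raise TypeError(f"not JSON serializable: {type(value)}")
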