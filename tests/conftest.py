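import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

HEALTHY = {
    "bmi": 22.0, "fpg": 5.0, "pg2h": np.nan, "sbp": 110.0, "dbp": 70.0,
    "tg": 0.9, "hdl": 1.5, "ldl": 2.6, "uric_acid": 250.0, "sex": "female",
    "smoker": 0, "drinker": 0, "drug_glucose": 0, "drug_bp": 0, "drug_lipid": 0,
}


def make_record(**over):
    """A single healthy female check-up record, overridable per field."""
    rec = dict(HEALTHY)
    rec.update(over)
    return rec


def make_visits(subject_id, visits):
    """Longitudinal rows for one subject: visits = [(time, age, overrides)]."""
    rows = []
    for t, age, over in visits:
        rec = make_record(**over)
        rec.update({"subject_id": subject_id, "visit_time": t, "age": age,
                    "geno_dose": over.get("geno_dose", 1)})
        rows.append(rec)
    return rows


SICK = {"bmi": 27.0, "fpg": 6.8, "sbp": 150.0, "dbp": 95.0, "tg": 2.2}


@pytest.fixture
def three_subject_frame():
    """One baseline-prevalent MetS subject, one incident at 1.5 y, one censored at 3 y."""
    rows = []
    rows += make_visits("prevalent", [(0.0, 40, dict(SICK)), (1.0, 41, dict(SICK))])
    rows += make_visits("incident", [(0.0, 50, {}), (1.5, 51.5, dict(SICK))])
    rows += make_visits("censored", [(0.0, 30, {}), (1.5, 31.5, {}), (3.0, 33, {})])
    return pd.DataFrame(rows)
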