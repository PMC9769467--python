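import pandas as pd
import pytest

from pufkit import CohortDataset
from pufkit.schema import VARIABLE_NAMES

#: A schema-valid hospitalized SUEP case used as the base for toy records.
BASE_RECORD = {
    "age_group": "40-59",
    "gender": "male",
    "quarter_first_diagnosis": "Q1",
    "year_first_diagnosis": "2021",
    "cohort": "SUEP",
    "mild_phase": "no",
    "moderate_phase": "yes",
    "severe_phase": "no",
    "patient_status_end_acute": "discharged",
    "hospitalization": "yes",
    "intensive_care": "no",
    "invasive_ventilation": "no",
    "followup_3m_available": "yes",
    "ability_to_work_3m": "yes",
    "any_symptom_3m": "no",
}


def make_dataset(overrides, dates=None, validate_columns=True):
    """Toy dataset builder: one record per dict of overrides of BASE_RECORD."""
    rows = [dict(BASE_RECORD, **o) for o in overrides]
    frame = pd.DataFrame(rows, columns=list(VARIABLE_NAMES))
    frame["case_id"] = [o.get("case_id", f"c{i:03d}") for i, o in enumerate(overrides)]
    if dates is not None:
        frame["diagnosis_date"] = pd.to_datetime(dates)
    return CohortDataset(frame)


@pytest.fixture(scope="session")
def small_synthetic():
    """One shared 2,000-record synthetic cohort (default config, fixed seed)."""
    from pufkit import synth

    return synth.generate_cohort(synth.default_config(2000, seed=11))
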