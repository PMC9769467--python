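"""Packaged reference tables of the published three-cohort registry snapshot.

Two data files ship with the package:

``cohort_reference_counts.csv``
    Per-cohort category counts of every release variable for the registry
    snapshot of 2022-03-15, in its original form (SUEP n=1,697, POP n=2,346,
    HAP n=519) and its anonymized public-use form (1,387 / 2,280 / 237).
    The follow-up sub-variables are counted among cases with an available
    3-month follow-up; their remainder is the structurally non-applicable
    ("n/a") group.

``variable_ratings.csv``
    Expert replicability/availability/distinguishability risk scores
    (1 = low, 2 = medium, 3 = high) for all 15 variables.

The counts double as ground truth for the synthetic generator's default
marginals and can be expanded into schema-valid datasets whose univariate
distributions reproduce the published tables exactly (cross-variable
structure beyond the deterministic n/a pattern is not represented).
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd

from .cohort import CohortDataset
from .errors import DataFormatError
from .schema import COHORTS, MISSING, NOT_APPLICABLE

#: Cohort sizes of the reference snapshot.
COHORT_TOTALS: dict[str, dict[str, int]] = {
    "original": {"SUEP": 1697, "POP": 2346, "HAP": 519},
    "anonymized": {"SUEP": 1387, "POP": 2280, "HAP": 237},
}

#: Variables whose structurally non-applicable remainder is padded as "n/a".
_NA_PADDED = {"ability_to_work_3m", "any_symptom_3m"}

_PHASE_FLAGS = {
    # most-severe phase -> (mild, moderate, severe) flags, cumulatively
    "mild": ("yes", "no", "no"),
    "moderate": ("no", "yes", "no"),
    "severe": ("no", "yes", "yes"),
    MISSING: (MISSING, MISSING, MISSING),
}


def _data_path(name: str):
    return resources.files("pufkit.data").joinpath(name)


@lru_cache(maxsize=None)
def reference_counts() -> pd.DataFrame:
    """The packaged count table (variable, category, per-cohort counts)."""
    with resources.as_file(_data_path("cohort_reference_counts.csv")) as p:
        return pd.read_csv(p, dtype={"variable": str, "category": str})


@lru_cache(maxsize=None)
def ratings_path() -> str:
    with resources.as_file(_data_path("variable_ratings.csv")) as p:
        return str(p)


def counts(variable: str, cohort: str, which: str = "original") -> pd.Series:
    """Counts of one variable in one cohort, indexed by category."""
    if which not in COHORT_TOTALS:
        raise DataFormatError(f"which must be original/anonymized, got {which!r}")
    table = reference_counts()
    rows = table[table["variable"] == variable]
    if rows.empty:
        raise DataFormatError(f"no reference counts for variable {variable!r}")
    return rows.set_index("category")[f"{cohort}_{which}"]


def _expand_column(variable: str, cohort: str, which: str, n: int) -> list[str]:
    c = counts(variable, cohort, which)
    values: list[str] = []
    for category, count in c.items():
        values.extend([category] * int(count))
    if len(values) > n:
        raise DataFormatError(f"{variable}/{cohort}: counts exceed cohort size")
    if len(values) < n:
        # n/a-padded variables owe their remainder to the non-applicable
        # group; elsewhere the (rare, off-by-one) remainder of the printed
        # table is assigned to the largest non-missing category.
        if variable in _NA_PADDED:
            pad = NOT_APPLICABLE
        else:
            pad = c.drop(labels=[MISSING], errors="ignore").idxmax()
        values.extend([pad] * (n - len(values)))
    return values


def reference_dataset(which: str = "original") -> CohortDataset:
    """Expand the published counts into a schema-valid dataset.

    Variables are expanded independently per cohort in stored category
    order, so univariate per-cohort counts are exact while joint structure
    is arbitrary — except the deterministic links: phase flags derive from
    the most-severe phase, and follow-up sub-variables are "n/a" exactly
    for the cases without an available follow-up.
    """
    pieces = []
    for cohort in COHORTS:
        n = COHORT_TOTALS[which][cohort]
        cols: dict[str, list[str]] = {"cohort": [cohort] * n}
        qy = _expand_column("quarter_year", cohort, which, n)
        cols["quarter_first_diagnosis"] = [
            v.split(" ")[0] if v != MISSING else MISSING for v in qy]
        cols["year_first_diagnosis"] = [
            v.split(" ")[1] if v != MISSING else MISSING for v in qy]
        severe = _expand_column("most_severe_phase", cohort, which, n)
        flags = [_PHASE_FLAGS[v] for v in severe]
        cols["mild_phase"] = [f[0] for f in flags]
        cols["moderate_phase"] = [f[1] for f in flags]
        cols["severe_phase"] = [f[2] for f in flags]
        for variable in ("age_group", "gender", "patient_status_end_acute",
                         "hospitalization", "intensive_care",
                         "invasive_ventilation", "followup_3m_available",
                         "ability_to_work_3m", "any_symptom_3m"):
            cols[variable] = _expand_column(variable, cohort, which, n)
        frame = pd.DataFrame(cols)
        frame["case_id"] = [f"{which[:4]}-{cohort}-{i:05d}" for i in range(n)]
        pieces.append(frame)
    return CohortDataset(pd.concat(pieces, ignore_index=True))
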