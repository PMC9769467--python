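"""Variable schema of the public-use-file (PUF) release format.

The release format carries 15 categorical variables per case: demographics
(age group, gender), the quarter and year of first diagnosis, the recruiting
sub-cohort, three disease-phase flags derived from the WHO Clinical
Progression Scale, the patient status at the end of the acute phase, acute
care indicators (hospitalization, intensive care, invasive ventilation), and
a 3-month follow-up block (availability, ability to work, any symptom).

Missing values are explicit category labels, not nulls: ``"unknown/missing"``
for undocumented values and ``"n/a"`` for structurally non-applicable ones
(follow-up sub-variables of cases without an available follow-up).  Making
missingness a first-class category keeps equivalence-class logic total.
"""

from __future__ import annotations

from dataclasses import dataclass

MISSING = "unknown/missing"
NOT_APPLICABLE = "n/a"

#: Names of the three recruiting sub-cohorts.
COHORTS = ("SUEP", "POP", "HAP")


@dataclass(frozen=True)
class VariableSchema:
    """One categorical variable of the release format."""

    name: str
    categories: tuple[str, ...]
    missing_label: str | None = MISSING
    ordinal: bool = False

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"{self.name}: duplicate category labels")
        if self.missing_label is not None and self.missing_label not in self.categories:
            raise ValueError(f"{self.name}: missing label not among categories")

    @property
    def substantive_categories(self) -> tuple[str, ...]:
        """Categories that carry information (neither missing nor n/a)."""
        drop = {self.missing_label, NOT_APPLICABLE}
        return tuple(c for c in self.categories if c not in drop)


def _v(name: str, categories: tuple[str, ...], *, missing: str | None = MISSING,
       ordinal: bool = False) -> VariableSchema:
    return VariableSchema(name, categories, missing_label=missing, ordinal=ordinal)


_YESNO = ("yes", "no", MISSING)

#: The 15 release variables, in canonical column order.
VARIABLES: tuple[VariableSchema, ...] = (
    _v("age_group", ("<=17", "18-39", "40-59", "60-79", ">=80", MISSING), ordinal=True),
    _v("gender", ("male", "female", "diverse", MISSING)),
    _v("quarter_first_diagnosis", ("Q1", "Q2", "Q3", "Q4", MISSING), ordinal=True),
    _v("year_first_diagnosis", ("2020", "2021", "2022", "2023", MISSING), ordinal=True),
    _v("cohort", COHORTS, missing=None),
    _v("mild_phase", _YESNO),
    _v("moderate_phase", _YESNO),
    _v("severe_phase", _YESNO),
    _v("patient_status_end_acute",
       ("ambulant", "discharged", "referral/transfer", "dead", MISSING)),
    _v("hospitalization", _YESNO),
    _v("intensive_care", _YESNO),
    _v("invasive_ventilation", _YESNO),
    _v("followup_3m_available", ("yes", "no/not yet"), missing=None),
    _v("ability_to_work_3m", (NOT_APPLICABLE, "yes", "no", MISSING)),
    _v("any_symptom_3m", (NOT_APPLICABLE, "yes", "no", MISSING)),
)

SCHEMA: dict[str, VariableSchema] = {v.name: v for v in VARIABLES}
VARIABLE_NAMES: tuple[str, ...] = tuple(SCHEMA)

#: Internal (never publicly released) columns.
CASE_ID = "case_id"
DIAGNOSIS_DATE = "diagnosis_date"

#: Default key (quasi-identifier) variables: high replicability/availability/
#: distinguishability demographics plus recruitment context.
DEFAULT_KEY_VARIABLES = (
    "age_group", "gender", "quarter_first_diagnosis", "year_first_diagnosis", "cohort",
)

#: Variables protected explicitly by t-closeness.
DEFAULT_SENSITIVE_VARIABLES = (
    "mild_phase", "moderate_phase", "severe_phase", "patient_status_end_acute",
    "intensive_care", "invasive_ventilation", "ability_to_work_3m", "any_symptom_3m",
)

#: Non-key variables protected only implicitly, through perfect correlation
#: with explicitly protected variables (hospitalization <-> mild phase,
#: follow-up availability <-> n/a pattern of the follow-up block).
DEFAULT_IMPLICIT_VARIABLES = ("hospitalization", "followup_3m_available")
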