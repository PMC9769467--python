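"""Seeded synthetic three-cohort generator.

Emulates a registry with three recruitment platforms — SUEP (cross-sectoral,
in- and outpatients), POP (population-based, survivors only, retrospective
follow-up) and HAP (high-resolution, hospitalized patients only).  Default
per-cohort category marginals are the published original-snapshot counts
(see :mod:`pufkit.reference`); outcome variables (intensive care, invasive
ventilation, death) are driven by logistic effect models with configurable
true log-odds, so downstream regression estimates have a known ground truth.

Per-record sampling order: cohort → quarter/year of diagnosis (joint
marginal) and a uniform date within that quarter → demographics →
most-severe disease phase → derived phase flags and hospitalization (mild
phase iff never hospitalized) → logistic outcome models → follow-up block
(sub-variables "n/a" iff no follow-up available).  Structural rules are
enforced afterwards and hold with probability 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CohortDataset
from .conditions import AGE_OVER_59, Condition, cond
from .errors import ConfigError
from . import reference
from .schema import (
    CASE_ID,
    COHORTS,
    DIAGNOSIS_DATE,
    MISSING,
    NOT_APPLICABLE,
    VARIABLE_NAMES,
)

#: Variables sampled directly from configured per-cohort marginals.
SAMPLED_VARIABLES = ("age_group", "gender", "quarter_year", "most_severe_phase",
                     "followup_3m_available")

_PHASE_FLAGS = {
    "mild": ("yes", "no", "no", "no"),        # mild, moderate, severe, hosp
    "moderate": ("no", "yes", "no", "yes"),
    "severe": ("no", "yes", "yes", "yes"),
    MISSING: (MISSING, MISSING, MISSING, MISSING),
}


@dataclass(frozen=True)
class LogisticEffect:
    """Bernoulli assignment of one category through a logistic model.

    Within ``subpopulation``, P(outcome = positive_category) =
    expit(intercept + Σ coef·[condition]); records drawn negative (and all
    records outside the subpopulation) are left to the variable's fallback
    fill.
    """

    outcome_variable: str
    positive_category: str
    subpopulation: Condition
    intercept: float
    terms: tuple[tuple[Condition, float], ...] = ()


@dataclass(frozen=True)
class StructuralRule:
    """Deterministic post-hoc constraint: when all conditions hold, force values."""

    when: tuple[Condition, ...]
    assign: tuple[tuple[str, str], ...]

    def apply(self, frame: pd.DataFrame) -> None:
        mask = np.ones(len(frame), dtype=bool)
        for c in self.when:
            mask &= c.mask(frame)
        for variable, value in self.assign:
            frame.loc[mask, variable] = value


#: Default structural constraints of the three platforms.
DEFAULT_RULES: tuple[StructuralRule, ...] = (
    # HAP recruits hospitalized patients only
    StructuralRule((cond("cohort", "HAP"), cond("hospitalization", "no", MISSING)),
                   (("hospitalization", "yes"), ("mild_phase", "no"),
                    ("moderate_phase", "yes"), ("severe_phase", "no"))),
    StructuralRule((cond("cohort", "HAP"), cond("patient_status_end_acute", "ambulant")),
                   (("patient_status_end_acute", "discharged"),)),
    # POP recruits survivors of the acute phase only
    StructuralRule((cond("cohort", "POP"), cond("patient_status_end_acute", "dead")),
                   (("patient_status_end_acute", "discharged"),)),
    # POP documents the follow-up retrospectively for everyone
    StructuralRule((cond("cohort", "POP"),),
                   (("followup_3m_available", "yes"),)),
    # follow-up sub-variables are structurally n/a without a follow-up
    StructuralRule((cond("followup_3m_available", "no/not yet"),),
                   (("ability_to_work_3m", NOT_APPLICABLE),
                    ("any_symptom_3m", NOT_APPLICABLE))),
)


@dataclass
class GeneratorConfig:
    n_total: int
    seed: int = 0
    cohort_mix: dict[str, float] = field(default_factory=dict)
    #: cohort -> variable -> {category: probability}; variables listed in
    #: SAMPLED_VARIABLES plus the conditional follow-up sub-variables.
    marginals: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    effects: tuple[LogisticEffect, ...] = ()
    #: cohort -> {category: probability} for hospitalized survivors' status.
    nonfatal_status: dict[str, dict[str, float]] = field(default_factory=dict)
    #: cohort -> variable -> missingness rate (overwrites with the missing label).
    missingness: dict[str, dict[str, float]] = field(default_factory=dict)
    rules: tuple[StructuralRule, ...] = DEFAULT_RULES

    def violations(self) -> list[str]:
        problems = []
        if self.n_total < 0:
            problems.append("n_total must be >= 0")
        if set(self.cohort_mix) != set(COHORTS):
            problems.append(f"cohort_mix must cover exactly {COHORTS}")
        vectors = [("cohort_mix", self.cohort_mix)]
        for cohort, per_var in self.marginals.items():
            vectors += [(f"{cohort}/{v}", probs) for v, probs in per_var.items()]
        for cohort, probs in self.nonfatal_status.items():
            vectors.append((f"{cohort}/nonfatal_status", probs))
        for name, probs in vectors:
            values = np.array(list(probs.values()), dtype=float)
            if (values < 0).any():
                problems.append(f"{name}: negative probability")
            elif values.size and not math.isclose(values.sum(), 1.0, abs_tol=1e-6):
                problems.append(f"{name}: probabilities sum to {values.sum():.6f}")
        for cohort, rates in self.missingness.items():
            for v, r in rates.items():
                if not 0 <= r <= 1:
                    problems.append(f"{cohort}/{v}: missingness rate {r} not in [0,1]")
        return problems


def _normalized(series: pd.Series) -> dict[str, float]:
    total = series.sum()
    return {str(k): float(v) / total for k, v in series.items()}


def default_config(n_total: int = 4562, seed: int = 0,
                   death_log_or: float = math.log(3.0)) -> GeneratorConfig:
    """Study-condition defaults: marginals transcribed from the published
    original per-cohort tables; a moderate age-over-59 effect on in-hospital
    death of plausible clinical magnitude (adjusted OR 3, configurable)."""
    totals = reference.COHORT_TOTALS["original"]
    grand = sum(totals.values())
    marginals: dict[str, dict[str, dict[str, float]]] = {}
    nonfatal: dict[str, dict[str, float]] = {}
    missingness: dict[str, dict[str, float]] = {}
    for cohort in COHORTS:
        per_var: dict[str, dict[str, float]] = {}
        for variable in SAMPLED_VARIABLES:
            per_var[variable] = _normalized(reference.counts(variable, cohort))
        for variable in ("ability_to_work_3m", "any_symptom_3m"):
            per_var[variable] = _normalized(reference.counts(variable, cohort))
        marginals[cohort] = per_var
        status = reference.counts("patient_status_end_acute", cohort)
        nonfatal[cohort] = _normalized(
            status.loc[["discharged", "referral/transfer"]])
        missingness[cohort] = {
            "patient_status_end_acute": float(status[MISSING]) / totals[cohort],
            "invasive_ventilation": float(
                reference.counts("invasive_ventilation", cohort)[MISSING])
            / totals[cohort],
        }
    effects = (
        LogisticEffect("intensive_care", "yes", cond("hospitalization", "yes"),
                       intercept=-2.2, terms=((cond("severe_phase", "yes"), 3.0),)),
        LogisticEffect("invasive_ventilation", "yes", cond("intensive_care", "yes"),
                       intercept=-0.4),
        LogisticEffect("patient_status_end_acute", "dead",
                       cond("hospitalization", "yes"),
                       intercept=-3.3, terms=((AGE_OVER_59, death_log_or),)),
    )
    return GeneratorConfig(
        n_total=n_total,
        seed=seed,
        cohort_mix={c: totals[c] / grand for c in COHORTS},
        marginals=marginals,
        effects=effects,
        nonfatal_status=nonfatal,
        missingness=missingness,
    )


def _sample(rng: np.random.Generator, probs: Mapping[str, float], size: int
            ) -> np.ndarray:
    cats = np.array(list(probs), dtype=object)
    p = np.array(list(probs.values()), dtype=float)
    return rng.choice(cats, size=size, p=p / p.sum())


def _quarter_start(label: str) -> pd.Timestamp:
    quarter, year = label.split(" ")
    return pd.Timestamp(int(year), 3 * (int(quarter[1]) - 1) + 1, 1)


def generate_cohort(config: GeneratorConfig, seed: int | None = None
                    ) -> CohortDataset:
    """Draw a fully reproducible synthetic dataset from ``config``."""
    problems = config.violations()
    if problems:
        raise ConfigError("invalid generator config: " + "; ".join(problems))
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_total
    frame = pd.DataFrame({v: pd.Series([""] * n, dtype=object)
                          for v in VARIABLE_NAMES})
    frame[CASE_ID] = [f"s{i:06d}" for i in range(n)]
    frame[DIAGNOSIS_DATE] = pd.NaT
    if n == 0:
        return CohortDataset(frame)

    frame["cohort"] = _sample(rng, config.cohort_mix, n)

    quarter_year = np.empty(n, dtype=object)
    for cohort in COHORTS:
        idx = np.flatnonzero(frame["cohort"].to_numpy() == cohort)
        if not idx.size:
            continue
        per_var = config.marginals[cohort]
        quarter_year[idx] = _sample(rng, per_var["quarter_year"], idx.size)
        for variable in ("age_group", "gender", "most_severe_phase",
                         "followup_3m_available"):
            frame.loc[idx, "_sev" if variable == "most_severe_phase" else variable] \
                = _sample(rng, per_var[variable], idx.size)

    dated = quarter_year != MISSING
    starts = pd.Series([_quarter_start(q) if d else pd.NaT
                        for q, d in zip(quarter_year, dated)])
    lengths = np.where(
        dated,
        [( _quarter_start(q) + pd.DateOffset(months=3) - _quarter_start(q)).days
         if d else 1 for q, d in zip(quarter_year, dated)],
        1)
    offsets = rng.integers(0, lengths)
    frame[DIAGNOSIS_DATE] = starts + pd.to_timedelta(offsets, unit="D")
    frame.loc[~dated, DIAGNOSIS_DATE] = pd.NaT
    frame["quarter_first_diagnosis"] = np.where(
        dated, [q.split(" ")[0] if d else MISSING for q, d in zip(quarter_year, dated)],
        MISSING)
    frame["year_first_diagnosis"] = np.where(
        dated, [q.split(" ")[1] if d else MISSING for q, d in zip(quarter_year, dated)],
        MISSING)

    flags = frame["_sev"].map(_PHASE_FLAGS)
    for i, variable in enumerate(("mild_phase", "moderate_phase", "severe_phase",
                                  "hospitalization")):
        frame[variable] = flags.str[i]
    frame = frame.drop(columns="_sev")

    frame["intensive_care"] = "no"
    frame["invasive_ventilation"] = "no"
    frame["patient_status_end_acute"] = ""
    for effect in config.effects:
        mask = effect.subpopulation.mask(frame)
        lp = np.full(n, effect.intercept)
        for condition, coef in effect.terms:
            lp += coef * condition.mask(frame)
        hit = mask & (rng.random(n) < expit(lp))
        frame.loc[hit, effect.outcome_variable] = effect.positive_category

    status = frame["patient_status_end_acute"].to_numpy(dtype=object)
    hosp = frame["hospitalization"].to_numpy()
    status[(hosp == "no") & (status == "")] = "ambulant"
    status[(hosp == MISSING) & (status == "")] = MISSING
    frame["patient_status_end_acute"] = status
    for cohort in COHORTS:
        open_idx = np.flatnonzero(
            (frame["cohort"].to_numpy() == cohort)
            & (frame["patient_status_end_acute"].to_numpy() == ""))
        if open_idx.size:
            frame.loc[open_idx, "patient_status_end_acute"] = _sample(
                rng, config.nonfatal_status[cohort], open_idx.size)

    for cohort in COHORTS:
        for variable, rate in config.missingness.get(cohort, {}).items():
            if rate > 0:
                hit = ((frame["cohort"].to_numpy() == cohort)
                       & (rng.random(n) < rate))
                frame.loc[hit, variable] = MISSING

    frame["ability_to_work_3m"] = NOT_APPLICABLE
    frame["any_symptom_3m"] = NOT_APPLICABLE
    available = frame["followup_3m_available"].to_numpy() == "yes"
    for cohort in COHORTS:
        idx = np.flatnonzero((frame["cohort"].to_numpy() == cohort) & available)
        if idx.size:
            per_var = config.marginals[cohort]
            frame.loc[idx, "ability_to_work_3m"] = _sample(
                rng, per_var["ability_to_work_3m"], idx.size)
            frame.loc[idx, "any_symptom_3m"] = _sample(
                rng, per_var["any_symptom_3m"], idx.size)

    for rule in config.rules:
        rule.apply(frame)
    return CohortDataset(frame)


def growth_prefixes(dataset: CohortDataset, step: int) -> list[CohortDataset]:
    """Nested prefixes of the diagnosis-date-ordered dataset.

    Sizes are step, 2·step, … plus the full dataset when its size is not a
    multiple of the step; undated records sort after all dated records,
    stably by case id.
    """
    if step < 1:
        raise ConfigError(f"step must be >= 1, got {step}")
    ordered = dataset.ordered()
    sizes = list(range(step, len(ordered) + 1, step))
    if not sizes or sizes[-1] != len(ordered):
        sizes.append(len(ordered))
    return [CohortDataset(ordered.frame.iloc[:s]) for s in sizes if s > 0]


def with_death_effect(config: GeneratorConfig, log_or: float) -> GeneratorConfig:
    """Copy of ``config`` with the age-over-59 death log-odds replaced."""
    effects = tuple(
        replace(e, terms=((AGE_OVER_59, log_or),))
        if e.outcome_variable == "patient_status_end_acute" else e
        for e in config.effects)
    return replace(config, effects=effects)
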