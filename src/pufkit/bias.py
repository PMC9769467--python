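"""Anonymization-induced statistical bias: tests, curves, effect estimates.

Quantifies how suppression changes what an analyst would estimate: category
distributions (Pearson chi-squared homogeneity tests), case fatality rates
and published fractions along a growing data stream, and age/gender-adjusted
logistic odds ratios with Wald confidence intervals.  Original and released
samples overlap, so the chi-squared independence assumption is formally
violated; the test is nonetheless applied as the conventional screen and the
caveat is documented rather than corrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2_contingency

from .anonymize import PrivacyConfig, release_stream
from .cohort import CohortDataset
from .conditions import AGE_OVER_59, Condition, cond
from .errors import ConfigError, DegenerateStatisticsError
from .schema import MISSING, NOT_APPLICABLE, SCHEMA
from .synth import growth_prefixes

#: Reference levels for covariate dummy coding.
REFERENCE_LEVELS = {"age_group": "18-39", "gender": "female"}


# ---------------------------------------------------------------------------
# distribution comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistributionComparison:
    variable: str
    categories: tuple[str, ...]
    counts_original: tuple[int, ...]
    counts_anonymized: tuple[int, ...]
    chi2_statistic: float
    degrees_of_freedom: int
    p_value: float

    def format_p(self) -> str:
        return "P < 0.001" if self.p_value < 0.001 else f"P = {self.p_value:.3f}"


def compare_distributions(original: CohortDataset, anonymized: CohortDataset,
                          variable: str, include_missing: bool = False,
                          ) -> DistributionComparison:
    """Chi-squared homogeneity test of one variable before/after release.

    Missing and n/a categories are excluded by default (they are reported
    descriptively, not tested); categories empty in both datasets are
    dropped, which sets the degrees of freedom to (#retained − 1).
    """
    if variable not in SCHEMA:
        raise ConfigError(f"unknown variable {variable!r}")
    spec = SCHEMA[variable]
    categories = list(spec.categories if include_missing
                      else spec.substantive_categories)
    o = original.frame[variable].value_counts().reindex(categories, fill_value=0)
    a = anonymized.frame[variable].value_counts().reindex(categories, fill_value=0)
    keep = (o + a) > 0
    o, a = o[keep], a[keep]
    if len(o) < 2:
        raise DegenerateStatisticsError(
            f"{variable}: fewer than 2 retained categories")
    if o.equals(a):
        chi2, p = 0.0, 1.0
    else:
        chi2, p, _, _ = chi2_contingency(np.array([o, a]), correction=False)
    return DistributionComparison(
        variable=variable,
        categories=tuple(o.index),
        counts_original=tuple(int(x) for x in o),
        counts_anonymized=tuple(int(x) for x in a),
        chi2_statistic=float(chi2),
        degrees_of_freedom=len(o) - 1,
        p_value=float(p),
    )


# ---------------------------------------------------------------------------
# case fatality rate
# ---------------------------------------------------------------------------

def case_fatality_rate(dataset: CohortDataset, cohorts: Sequence[str],
                       ) -> tuple[float, int, int]:
    """(CFR, deaths, cases with known status) over the selected cohorts."""
    if not cohorts:
        raise ConfigError("cohorts must be nonempty")
    frame = dataset.frame
    sub = frame[frame["cohort"].isin(set(cohorts))]
    status = sub["patient_status_end_acute"]
    denominator = int((status != MISSING).sum())
    if denominator == 0:
        raise DegenerateStatisticsError("CFR undefined: no known-status cases")
    numerator = int((status == "dead").sum())
    return numerator / denominator, numerator, denominator


@dataclass(frozen=True)
class CFRCurve:
    """CFR before/after release along a growing stream; bias = after − before."""

    points: pd.DataFrame  # columns: size, cfr_original, cfr_anonymized, bias
    excluded_sizes: tuple[int, ...]
    median_abs_bias: float
    iqr_abs_bias: tuple[float, float]
    denominator_rule: str = "cases with known patient status"


def cfr_bias_curve(dataset: CohortDataset, config: PrivacyConfig,
                   cohorts: Sequence[str], step: int) -> CFRCurve:
    """CFR bias per prefix size under incremental release, with summaries.

    Sizes where the released subset has no known-status case in the selected
    cohorts are flagged and excluded from the summary statistics.
    """
    prefixes = growth_prefixes(dataset, step)
    releases = release_stream(prefixes, config)
    rows, excluded = [], []
    for prefix, release in zip(prefixes, releases):
        size = len(prefix)
        try:
            cfr_orig, _, _ = case_fatality_rate(prefix, cohorts)
            cfr_anon, _, _ = case_fatality_rate(
                release.released_dataset(prefix), cohorts)
        except DegenerateStatisticsError:
            excluded.append(size)
            continue
        rows.append((size, cfr_orig, cfr_anon, cfr_anon - cfr_orig))
    points = pd.DataFrame(rows, columns=["size", "cfr_original",
                                         "cfr_anonymized", "bias"])
    abs_bias = points["bias"].abs()
    if len(points):
        median = float(abs_bias.median())
        iqr = (float(abs_bias.quantile(0.25)), float(abs_bias.quantile(0.75)))
    else:
        median, iqr = float("nan"), (float("nan"), float("nan"))
    return CFRCurve(points, tuple(excluded), median, iqr)


# ---------------------------------------------------------------------------
# published fraction
# ---------------------------------------------------------------------------

def fraction_published_curve(dataset: CohortDataset, config: PrivacyConfig,
                             step: int) -> pd.DataFrame:
    """Released count and fraction per growth prefix, overall and per cohort."""
    prefixes = growth_prefixes(dataset, step)
    releases = release_stream(prefixes, config)
    rows = []
    for prefix, release in zip(prefixes, releases):
        row = {"size": len(prefix), "released": len(release.released_ids)}
        row["fraction"] = row["released"] / row["size"] if row["size"] else 0.0
        cohorts = prefix.frame.set_index("case_id")["cohort"]
        for cohort in SCHEMA["cohort"].categories:
            total = int((cohorts == cohort).sum())
            got = int(cohorts.loc[list(release.released_ids)].eq(cohort).sum())
            row[f"size_{cohort}"] = total
            row[f"released_{cohort}"] = got
            row[f"fraction_{cohort}"] = got / total if total else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# adjusted odds ratios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectEstimate:
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_used: int
    converged: bool
    descriptor: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ModelSpec:
    """One adjusted logistic model: outcome ~ exposure + covariate dummies."""

    name: str
    outcome: Condition
    exposure: Condition
    covariates: tuple[str, ...] = ()
    subpopulation: tuple[Condition, ...] = ()


def _complete_cases(frame: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    for v in variables:
        frame = frame[~frame[v].isin({MISSING, NOT_APPLICABLE})]
    return frame


def adjusted_or(dataset: CohortDataset, outcome: Condition, exposure: Condition,
                covariates: Sequence[str] = (),
                subpopulation: Sequence[Condition] = ()) -> EffectEstimate:
    """Maximum-likelihood logistic fit; OR of the exposure with 95% Wald CI.

    Cases with unknown/missing (or structurally n/a) values in any involved
    variable are excluded (complete-case analysis).  Separation or
    non-convergence yields a flagged estimate, never a silent fallback.
    """
    frame = dataset.frame
    for condition in subpopulation:
        frame = frame[condition.mask(frame)]
    involved = [outcome.variable, exposure.variable, *covariates]
    frame = _complete_cases(frame, involved).reset_index(drop=True)

    y = outcome.mask(frame).astype(float)
    x = exposure.mask(frame).astype(float)
    if len(np.unique(y)) < 2 or len(np.unique(x)) < 2:
        raise DegenerateStatisticsError(
            "both outcome and exposure levels must be present after filtering")
    table = pd.crosstab(y, x)
    if (table == 0).any().any():
        zero = [(o, e) for o in table.index for e in table.columns
                if table.loc[o, e] == 0]
        raise DegenerateStatisticsError(
            f"empty outcome/exposure cell(s) after filtering: {zero}")

    X = pd.DataFrame({"const": 1.0, "exposure": x})
    for covariate in covariates:
        ref = REFERENCE_LEVELS.get(
            covariate, SCHEMA[covariate].substantive_categories[0])
        present = [c for c in SCHEMA[covariate].substantive_categories
                   if c != ref and (frame[covariate] == c).any()]
        for category in present:
            X[f"{covariate}[{category}]"] = (frame[covariate] == category).astype(float)

    descriptor = {
        "outcome": outcome.describe(),
        "exposure": exposure.describe(),
        "covariates": list(covariates),
        "subpopulation": [c.describe() for c in subpopulation],
    }
    converged = True
    try:
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            result = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(result.mle_retvals.get("converged", False))
        beta = float(result.params["exposure"])
        ci = result.conf_int().loc["exposure"]
        lo, hi = float(ci[0]), float(ci[1])
        if not np.isfinite([beta, lo, hi]).all():
            converged = False
    except Exception:
        converged, beta, lo, hi = False, float("nan"), float("nan"), float("nan")
    with np.errstate(over="ignore"):
        return EffectEstimate(
            odds_ratio=float(np.exp(beta)), ci_low=float(np.exp(lo)),
            ci_high=float(np.exp(hi)), n_used=len(frame), converged=converged,
            descriptor=descriptor)


@dataclass(frozen=True)
class DeviationSummary:
    median_abs_dev: float
    min_abs_dev: float
    max_abs_dev: float
    n_pairs: int


def deviation_summary(pairs: Sequence[tuple[float, float]]) -> DeviationSummary:
    """Median/min/max absolute deviation over paired before/after odds ratios."""
    if not pairs:
        raise DegenerateStatisticsError("no odds-ratio pairs to summarize")
    devs = np.abs([a - b for b, a in pairs])
    return DeviationSummary(float(np.median(devs)), float(devs.min()),
                            float(devs.max()), len(devs))


@dataclass(frozen=True)
class OrComparisonCurve:
    spec: ModelSpec
    rows: pd.DataFrame  # size, or_original, or_anonymized, ci bounds, deviation
    gaps: tuple[int, ...]
    summary: DeviationSummary | None


def or_comparison_curve(dataset: CohortDataset, config: PrivacyConfig,
                        spec: ModelSpec, step: int) -> OrComparisonCurve:
    """Fit the model on each growth prefix and on its incremental release.

    Sizes where either fit is impossible or non-convergent are recorded as
    gaps (the corresponding snapshots simply lack the relevant information)
    and excluded from the deviation summary.
    """
    prefixes = growth_prefixes(dataset, step)
    releases = release_stream(prefixes, config)
    rows, gaps, pairs = [], [], []
    for prefix, release in zip(prefixes, releases):
        size = len(prefix)
        try:
            before = adjusted_or(prefix, spec.outcome, spec.exposure,
                                 spec.covariates, spec.subpopulation)
            after = adjusted_or(release.released_dataset(prefix), spec.outcome,
                                spec.exposure, spec.covariates,
                                spec.subpopulation)
        except DegenerateStatisticsError:
            gaps.append(size)
            continue
        if not (before.converged and after.converged):
            gaps.append(size)
            continue
        pairs.append((before.odds_ratio, after.odds_ratio))
        rows.append({
            "size": size,
            "or_original": before.odds_ratio,
            "ci_low_original": before.ci_low,
            "ci_high_original": before.ci_high,
            "or_anonymized": after.odds_ratio,
            "ci_low_anonymized": after.ci_low,
            "ci_high_anonymized": after.ci_high,
            "deviation": abs(after.odds_ratio - before.odds_ratio),
        })
    summary = deviation_summary(pairs) if pairs else None
    return OrComparisonCurve(spec, pd.DataFrame(rows), tuple(gaps), summary)


#: Desk-scale analogues of the published regression questions (the published
#: 49-59-year age band is not representable in the released categories and
#: is deliberately not attempted).
DEFAULT_MODEL_SPECS: tuple[ModelSpec, ...] = (
    ModelSpec("death_age_inpatient_suep",
              outcome=cond("patient_status_end_acute", "dead"),
              exposure=AGE_OVER_59,
              covariates=("gender",),
              subpopulation=(cond("cohort", "SUEP"), cond("hospitalization", "yes"))),
    ModelSpec("symptom_gender_pop",
              outcome=cond("any_symptom_3m", "yes"),
              exposure=cond("gender", "female"),
              covariates=("age_group",),
              subpopulation=(cond("cohort", "POP"),)),
    ModelSpec("icu_age_hap",
              outcome=cond("intensive_care", "yes"),
              exposure=AGE_OVER_59,
              covariates=("gender",),
              subpopulation=(cond("cohort", "HAP"),)),
)
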