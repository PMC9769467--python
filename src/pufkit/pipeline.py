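"""End-to-end pipeline and report assembly.

``run_pipeline`` chains generate/load → variable triage → incremental
anonymization over a growing stream → risk profiling → bias evaluation, all
driven by one seed, and writes a deterministic report (CSV/JSON, optional
plots).  All randomness flows from the single pipeline seed; sub-seeds are
derived per stage name so stages can be rerun in isolation.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
import pandas as pd
import yaml

from . import bias, risk, synth
from .triage import load_ratings, triage as run_triage
from .anonymize import AnonymizedRelease, PrivacyConfig, release_stream
from .cohort import CohortDataset, read_puf_csv, write_puf_csv
from .errors import DegenerateStatisticsError, PufError, ConfigError
from .schema import COHORTS, NOT_APPLICABLE, SCHEMA, VARIABLE_NAMES

log = logging.getLogger("pufkit")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (stable across runs and platforms)."""
    return (seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Exactly one of ``generator`` / ``input_path`` selects the data source."""

    generator: synth.GeneratorConfig | None = None
    input_path: str | None = None
    ratings_path: str | None = None
    k: int = 11
    t: float = 0.5
    step: int = 250
    cfr_cohorts: tuple[str, ...] = ("SUEP", "HAP")
    model_specs: tuple[bias.ModelSpec, ...] = bias.DEFAULT_MODEL_SPECS
    seed: int = 0
    output_dir: str = "results/pipeline"
    make_plots: bool = True

    def __post_init__(self) -> None:
        if (self.generator is None) == (self.input_path is None):
            raise ConfigError(
                "exactly one of generator settings or input path must be given")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        generator = None
        if "generator" in raw:
            g = raw.pop("generator") or {}
            generator = synth.default_config(
                n_total=int(g.get("n_total", 4562)),
                seed=int(g.get("seed", raw.get("seed", 0))))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(generator=generator, **raw)


@dataclass
class BiasReport:
    """All artifacts of one pipeline run."""

    original: CohortDataset
    released: CohortDataset
    release: AnonymizedRelease
    cohort_table: pd.DataFrame
    distribution_tests: pd.DataFrame
    fraction_curve: pd.DataFrame
    cfr_curve: bias.CFRCurve
    risk_before: risk.RiskProfile
    risk_after: risk.RiskProfile
    model_comparisons: list[bias.OrComparisonCurve]
    audit: list[dict] = field(default_factory=list)


def _fmt_cell(count: int, base: int) -> str:
    if base == 0:
        return "0 (—)" if count == 0 else f"{count} (—)"
    return f"{count} ({100 * count / base:.1f}%)"


def render_cohort_table(original: CohortDataset, anonymized: CohortDataset,
                        ) -> pd.DataFrame:
    """Per-variable, per-cohort count (percentage) description table.

    Percentage bases are the cohort's dataset size; for the follow-up
    sub-variables the base excludes structurally non-applicable cases, so
    percentages refer to cases with an available follow-up.
    """
    columns: dict[tuple[str, str], dict[tuple[str, str], str]] = {}
    for label, dataset in (("original", original), ("anonymized", anonymized)):
        for cohort in COHORTS:
            sub = dataset.frame[dataset.frame["cohort"] == cohort]
            cells: dict[tuple[str, str], str] = {}
            for variable in VARIABLE_NAMES:
                if variable == "cohort":
                    continue
                counts = sub[variable].value_counts()
                base = int(len(sub) - counts.get(NOT_APPLICABLE, 0))
                for category in SCHEMA[variable].categories:
                    if category == NOT_APPLICABLE:
                        continue
                    cells[(variable, category)] = _fmt_cell(
                        int(counts.get(category, 0)), base)
            columns[(label, cohort)] = cells
    table = pd.DataFrame(columns)
    table.index = pd.MultiIndex.from_tuples(table.index,
                                            names=("variable", "category"))
    table.columns = pd.MultiIndex.from_tuples(table.columns,
                                              names=("dataset", "cohort"))
    return table


def run_pipeline(config: PipelineConfig) -> BiasReport:
    """Execute the full procedure and write the report to ``output_dir``."""
    stage = "load"
    try:
        if config.generator is not None:
            stage = "generate"
            dataset = synth.generate_cohort(
                config.generator, seed=stage_seed(config.seed, "generate"))
        else:
            dataset = read_puf_csv(config.input_path)
        log.info("dataset: %d records", len(dataset))

        stage = "triage"
        triage_result = run_triage(load_ratings(config.ratings_path))
        privacy = PrivacyConfig(
            k=config.k, t=config.t,
            key_variables=tuple(sorted(triage_result.key_variables)),
            sensitive_variables=tuple(sorted(triage_result.sensitive_variables)))

        stage = "anonymize"
        prefixes = synth.growth_prefixes(dataset, config.step)
        releases = release_stream(prefixes, privacy)
        release = releases[-1]
        released = release.released_dataset(dataset)
        for decision in release.class_decisions.values():
            log.info("class %s size=%d -> %s", decision.key_tuple,
                     decision.size, decision.status)

        stage = "risk"
        risk_before = risk.reidentification_risks(dataset, privacy.key_variables)
        risk_after = (risk.reidentification_risks(released, privacy.key_variables)
                      if len(released) else None)

        stage = "evaluate"
        tests = []
        for variable in VARIABLE_NAMES:
            if variable == "cohort":
                continue
            try:
                c = bias.compare_distributions(dataset, released, variable)
            except DegenerateStatisticsError:
                continue
            tests.append({"variable": variable, "chi2": c.chi2_statistic,
                          "df": c.degrees_of_freedom, "p_value": c.p_value,
                          "p_formatted": c.format_p()})
        report = BiasReport(
            original=dataset,
            released=released,
            release=release,
            cohort_table=render_cohort_table(dataset, released),
            distribution_tests=pd.DataFrame(tests),
            fraction_curve=bias.fraction_published_curve(dataset, privacy,
                                                         config.step),
            cfr_curve=bias.cfr_bias_curve(dataset, privacy, config.cfr_cohorts,
                                          config.step),
            risk_before=risk_before,
            risk_after=risk_after,
            model_comparisons=[
                bias.or_comparison_curve(dataset, privacy, spec, config.step)
                for spec in config.model_specs],
            audit=release.audit_records(),
        )
    except PufError:
        raise
    except Exception as exc:
        raise PufError(f"pipeline stage {stage!r} failed: {exc}") from exc
    _write_report(report, config)
    return report


def _write_report(report: BiasReport, config: PipelineConfig) -> None:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_puf_csv(report.released, outdir / "puf.csv", include_date=False)
    report.cohort_table.to_csv(outdir / "cohort_table.csv")
    report.distribution_tests.to_csv(outdir / "distribution_tests.csv", index=False)
    report.fraction_curve.to_csv(outdir / "fraction_curve.csv", index=False)
    report.cfr_curve.points.to_csv(outdir / "cfr_curve.csv", index=False)
    risk_payload = {
        "before": report.risk_before.as_percentages(),
        "after": report.risk_after.as_percentages() if report.risk_after else None,
    }
    models_payload = []
    for comparison in report.model_comparisons:
        models_payload.append({
            "name": comparison.spec.name,
            "gaps": list(comparison.gaps),
            "summary": None if comparison.summary is None else {
                "median_abs_dev": comparison.summary.median_abs_dev,
                "min_abs_dev": comparison.summary.min_abs_dev,
                "max_abs_dev": comparison.summary.max_abs_dev,
                "n_pairs": comparison.summary.n_pairs,
            },
            "rows": comparison.rows.to_dict(orient="records"),
        })
    summary = {
        "n_original": len(report.original),
        "n_released": len(report.released),
        "fraction_released": len(report.released) / max(len(report.original), 1),
        "cfr_median_abs_bias": report.cfr_curve.median_abs_bias,
        "suppressed_by_reason": _suppression_totals(report.audit),
    }
    for name, payload in (("risk.json", risk_payload),
                          ("models.json", models_payload),
                          ("audit.json", report.audit),
                          ("summary.json", summary)):
        with open(outdir / name, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
    if config.make_plots:
        _plots(report, outdir)


def _suppression_totals(audit: list[dict]) -> dict[str, int]:
    totals: dict[str, int] = {}
    for entry in audit:
        n = entry["size"] - entry["n_released"]
        totals[entry["status"]] = totals.get(entry["status"], 0) + max(n, 0)
    return totals


def _plots(report: BiasReport, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(report.fraction_curve["size"], report.fraction_curve["fraction"],
            marker="o", ms=3)
    ax.set_xlabel("original dataset size")
    ax.set_ylabel("fraction released")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    fig.savefig(outdir / "fraction_curve.png", dpi=120)
    plt.close(fig)

    points = report.cfr_curve.points
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(points["size"], 100 * points["cfr_original"], label="original")
    ax.plot(points["size"], 100 * points["cfr_anonymized"], label="released")
    ax.set_xlabel("original dataset size")
    ax.set_ylabel("case fatality rate (%)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "cfr_curve.png", dpi=120)
    plt.close(fig)
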