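"""Quantify the statistical bias introduced by suppression.

Compares the synthetic stream with its incremental release: chi-squared
distribution tests per variable, the case-fatality-rate bias curve for the
two cohorts that contain fatalities (SUEP + HAP), and the age/gender-
adjusted odds-ratio comparisons over growing dataset sizes.  Writes tables
under results/ and prints the headline summaries.
"""

import json
from pathlib import Path

import pandas as pd

from pufkit import (
    PrivacyConfig,
    anonymize,
    cfr_bias_curve,
    compare_distributions,
    or_comparison_curve,
    read_puf_csv,
    render_cohort_table,
    synth,
)
from pufkit.bias import DEFAULT_MODEL_SPECS
from pufkit.errors import DegenerateStatisticsError
from pufkit.schema import VARIABLE_NAMES

OUT = Path("results")
STEP = 250


def main() -> None:
    OUT.mkdir(exist_ok=True)
    path = OUT / "synthetic_cohort.csv"
    dataset = (read_puf_csv(path) if path.exists()
               else synth.generate_cohort(synth.default_config(4562, seed=7)))
    config = PrivacyConfig()
    release = anonymize(dataset, config)
    released = release.released_dataset(dataset)

    render_cohort_table(dataset, released).to_csv(OUT / "cohort_table.csv")

    rows = []
    for variable in VARIABLE_NAMES:
        if variable == "cohort":
            continue
        try:
            c = compare_distributions(dataset, released, variable)
        except DegenerateStatisticsError:
            continue
        rows.append({"variable": variable, "chi2": round(c.chi2_statistic, 3),
                     "df": c.degrees_of_freedom, "p": c.format_p()})
    tests = pd.DataFrame(rows)
    tests.to_csv(OUT / "distribution_tests.csv", index=False)
    significant = (tests["p"].str.contains("<")
                   | (tests["p"].str.extract(r"= (.+)")[0].astype(float) < 0.05))
    print(f"distribution tests: {int(significant.sum())}/{len(tests)} variables "
          "differ at P < 0.05 between original and released data")

    curve = cfr_bias_curve(dataset, config, ("SUEP", "HAP"), STEP)
    curve.points.to_csv(OUT / "cfr_curve.csv", index=False)
    final = curve.points.iloc[-1]
    print(f"CFR at full size: {100 * final.cfr_original:.1f}% original vs "
          f"{100 * final.cfr_anonymized:.1f}% released "
          f"(median |bias| over sizes: {100 * curve.median_abs_bias:.2f} pp)")

    models = []
    for spec in DEFAULT_MODEL_SPECS:
        comparison = or_comparison_curve(dataset, config, spec, STEP)
        comparison.rows.to_csv(OUT / f"or_curve_{spec.name}.csv", index=False)
        summary = comparison.summary
        models.append({
            "model": spec.name,
            "n_sizes": len(comparison.rows),
            "gaps": len(comparison.gaps),
            "median_abs_dev": None if summary is None
            else round(summary.median_abs_dev, 3),
            "max_abs_dev": None if summary is None
            else round(summary.max_abs_dev, 3),
        })
        if summary is not None:
            print(f"model {spec.name}: median |OR deviation| "
                  f"{summary.median_abs_dev:.3f} "
                  f"(min {summary.min_abs_dev:.3f}, max {summary.max_abs_dev:.3f})")
        else:
            print(f"model {spec.name}: no size with both fits available")
    (OUT / "models.json").write_text(json.dumps(models, indent=2))
    print(f"wrote tables to {OUT}/")


if __name__ == "__main__":
    main()
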