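"""Generate the default synthetic three-cohort registry stream.

Draws n = 4,562 cases (the size of the reference snapshot) with per-cohort
marginals matching the published original tables, and writes the private
dataset (with diagnosis dates and case ids) to results/synthetic_cohort.csv.
"""

from pathlib import Path

from pufkit import synth, validate_dataset, write_puf_csv

OUT = Path("results")
SEED = 7


def main() -> None:
    OUT.mkdir(exist_ok=True)
    dataset = synth.generate_cohort(synth.default_config(4562, seed=SEED))
    violations = validate_dataset(dataset)
    frame = dataset.frame
    pop = frame[frame.cohort == "POP"]
    hap = frame[frame.cohort == "HAP"]
    write_puf_csv(dataset, OUT / "synthetic_cohort.csv", include_date=True)
    print(f"generated {len(dataset)} cases -> {OUT/'synthetic_cohort.csv'}")
    print(f"schema violations: {len(violations)}")
    print(f"POP deaths (must be 0): {(pop.patient_status_end_acute == 'dead').sum()}")
    print(f"HAP hospitalized fraction (must be 1): "
          f"{(hap.hospitalization == 'yes').mean():.3f}")


if __name__ == "__main__":
    main()
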