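# pufkit

Suppression-based anonymization for open clinical datasets, and the tools to
measure what that anonymization does to statistics computed from them.

Large COVID-19 registries release *public use files* (PUFs): openly
downloadable, patient-level extracts with a handful of categorical variables
(age group, gender, quarter/year of diagnosis, recruiting cohort, disease
severity and outcome indicators, 3-month follow-up block). Publishing
patient-level rows without consent-per-download requires mathematical
disclosure control — and disclosure control suppresses records, which biases
every statistic an analyst later computes. `pufkit` implements both halves
of that trade-off for a three-cohort registry setting (a cross-sectoral
platform SUEP, a population-based platform POP that recruits survivors only,
and a high-resolution platform HAP of hospitalized patients only):

- **Variable triage.** Every released variable is scored 1–3 on
  *replicability* (R), *availability* (A) and *distinguishability* (D).
  Variables with R + A + D > 5 are **key variables** (quasi-identifiers);
  the rest are **sensitive**, except those implicitly protected through
  perfect correlation with another protected variable.
- **Anonymization engine.** A record is released iff its *equivalence
  class* (records identical on all key variables) satisfies
  **k-anonymity** (|class| ≥ k, default k = 11) and **t-closeness** (for
  every sensitive variable, the class distribution is within distance
  t = 0.5 of the full-dataset distribution; total-variation distance for
  nominal variables, normalized earth-mover distance for ordinal ones).
  Failing classes are withheld whole — suppression only, no value
  generalization. An **incremental mode** replays a growing stream without
  ever retracting a released record.
- **Risk assessment.** Prosecutor-model re-identification risk: a record's
  risk is 1/|class|; the profile reports max = 1/min|class|,
  min = 1/max|class| and the record-weighted average n_classes/n_records.
  With k = 11, no released record can exceed 1/11 = 9.09 %.
- **Bias evaluation.** χ² homogeneity tests per variable, released-fraction
  and case-fatality-rate (CFR = deaths / known-status cases) curves along
  the growing stream, and age/gender-adjusted logistic odds ratios with
  95 % Wald CIs, compared before vs. after suppression.
- **Synthetic generator.** A seeded three-cohort generator whose default
  marginals are transcribed from the published registry snapshot
  (n = 4,562) and whose outcomes follow configurable logistic models, so
  every claim above is testable without access to restricted data.

## Worked example

The numbered drivers under `analysis/` run the study end to end and write
their tables under `results/`:

```bash
python analysis/01_generate_cohort.py
python analysis/02_triage_variables.py
python analysis/03_anonymize_release.py
python analysis/04_risk_profile.py
python analysis/05_bias_evaluation.py
```

Output of a complete run (seed 7):

```
generated 4562 cases -> results/synthetic_cohort.csv
schema violations: 0
POP deaths (must be 0): 0
HAP hospitalized fraction (must be 1): 1.000
key variables (5): age_group, cohort, gender, quarter_first_diagnosis, year_first_diagnosis
implicitly protected: followup_3m_available, hospitalization
released 3745/4562 cases (82.1%) -> results/puf.csv
classes: 196 total, 2 frozen
max risk before: 100.0%  after: 9.09%
avg risk before: 4.3%  after: 1.82%
distribution tests: 11/14 variables differ at P < 0.05 between original and released data
CFR at full size: 5.2% original vs 5.3% released (median |bias| over sizes: 0.47 pp)
model death_age_inpatient_suep: median |OR deviation| 0.696 (min 0.028, max 1.101)
model symptom_gender_pop: median |OR deviation| 0.005 (min 0.000, max 0.054)
```

Reading this: the stream of 4,562 synthetic cases obeys its structural
constraints exactly; triage flags the five demographic/recruitment
variables as quasi-identifiers; incremental k = 11 / t = 0.5 suppression
publishes 82 % of cases (two classes were frozen when accruing data pushed
them past t — flagged, never retracted); the worst-case re-identification
risk drops from 100 % (key-unique records exist) to the 9.09 % ceiling;
and although most value *distributions* shift detectably (χ² at P < 0.05),
the *statistics* barely move — the CFR changes by half a percentage point
at the median, and a prevalent-outcome odds ratio (any symptom at follow-up
in POP) deviates by 0.005 at the median. Rare-event models on small strata
(in-hospital death among SUEP inpatients) deviate more at small sizes, and
shrink toward the original estimate as cases accrue.

The same pipeline is scriptable (`pufkit generate|triage|anonymize|risk|
evaluate|report|pipeline`, see `pufkit --help`) and callable as a library
(`pufkit.anonymize`, `pufkit.reidentification_risks`,
`pufkit.cfr_bias_curve`, …).

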