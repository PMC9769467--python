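# Methods

## The release procedure

The data model is a flat table of cases with 15 categorical variables.
Missingness is categorical, not null: `"unknown/missing"` for undocumented
values and `"n/a"` for structurally non-applicable ones (the 3-month
follow-up sub-variables of cases without an available follow-up). This
makes every operation total — equivalence classes, distributions and
distances are defined for every record without imputation or dropping.

**Triage.** Disclosure risk is attributed per variable by three expert
scores in {1, 2, 3}: replicability (is the value stable over time, so an
attacker could observe it again), availability (could it be learned from
external sources or appearance) and distinguishability (how finely it
partitions the population). A variable is a key variable iff
R + A + D > 5. With the packaged ratings this yields exactly
{age group, gender, quarter of diagnosis, year of diagnosis, cohort}.
Triage is expert input by design; the package validates and applies
ratings, it does not estimate them from data. Two non-key variables
(hospitalization, follow-up availability) are declared *implicitly*
protected: hospitalization is a deterministic function of the mild-phase
flag and the follow-up availability is readable off the n/a pattern of the
follow-up block, so protecting their correlates protects them. The
implicit set is an explicit override list, not an inferred one.

**Suppression rule.** Let an equivalence class be the set of records
identical on all key variables (missing labels compare as ordinary
categories — groups of jointly missing quarters are suppressed or released
together). A class is released iff

1. |class| ≥ k (default k = 11), and
2. for every sensitive variable, d(class distribution, full-dataset
   distribution) ≤ t (default t = 0.5),

and suppressed whole otherwise. Released records are unmodified; all
coarsening (age into five bands, dates into quarters) is fixed upstream in
the schema. Releasing a ≥ k subset of a failing class would require a
selection rule with its own disclosure analysis, so partial classes are
deliberately not offered; class-level decisions make both guarantees
verifiable by a one-line recheck.

Distance d is the total-variation distance ½·Σ|p−q| for nominal variables
and, for variables declared ordinal, the normalized earth-mover distance
Σ|cumsum(p−q)|/(m−1), which is 1 exactly when the class and the reference
sit on opposite extreme categories. The boundary is inclusive (d = t
releases). By default all eight sensitive variables are treated as nominal:
each is either binary-plus-missing or an unordered status, where imposing
an order for the EMD would be arbitrary; the ordinal path is available per
variable through `PrivacyConfig.ordinal_sensitive`. The reference
distribution is the sensitive variable's distribution over the *full
original input dataset*, not the released subset, because the inference
attack being countered is against the underlying population.

**Continuous release.** Registries publish growing snapshots. Class
decisions are recomputed on each cumulative snapshot; the invariants
maintained are (i) released sets are nested across releases — nothing is
ever retracted — and (ii) every newly released record belongs to a class
that satisfies both criteria on its snapshot. Because classes only grow,
k-anonymity can never newly fail; t-closeness can, since the reference
distribution drifts as data accrue. A previously released class that now
fails t is *frozen*: its previously released members remain public (they
already are), no new members are added, and the event is flagged in the
audit trail with the offending variable and distance. Freezing is the only
point where the published union is not re-certified against the *current*
reference; it is reported, never silent.

**Risk.** Prosecutor model: the attacker knows a target's key values and
that the target is in the data, so the per-record risk is 1/|class|. The
profile reports the maximum, the minimum, and the record-weighted average
(= n_classes / n_records). The averaging convention is a choice; the
class-weighted mean of 1/|class| is available behind a flag. Risks are
reported as percentages with two decimals.

## Bias evaluation

- **χ² tests.** Pearson homogeneity test on the before/after count vectors
  per variable (`scipy.stats.chi2_contingency`, no continuity correction).
  Missing/n/a categories are excluded by default (togglable) and
  categories empty in both datasets are dropped, so df = retained − 1.
  The two samples overlap (the released set is a subset of the original),
  which violates the independence assumption of the test; it is applied
  regardless as the conventional screen, and P-values should be read as
  descriptive. P is formatted to three decimals, "P < 0.001" below that.
- **CFR.** deaths / cases with known patient status, over a cohort
  selection (the survivor-only POP is excluded from CFR analyses by
  construction). The bias curve replays the stream, anonymizes
  incrementally, and records CFR(original prefix) vs CFR(released prefix);
  sizes with no known-status released case are flagged and excluded from
  the median/IQR summaries.
- **Odds ratios.** Maximum-likelihood logistic regression
  (`statsmodels.Logit`) of a binary outcome condition on a binary exposure
  condition plus indicator dummies for categorical covariates (reference
  levels: age "18-39", gender "female"; only levels present in the data
  enter, to avoid degenerate columns). Complete-case analysis: records
  with missing or n/a values in any involved variable are dropped, and
  n_used is reported. CIs are 95 % Wald intervals on the log-odds scale;
  profile likelihood is not offered. Separation and non-convergence
  produce a *flagged* estimate (`converged=False`) — never a silent
  fallback — and flagged sizes appear as gaps in the comparison curves.

## The synthetic generator

The generator emulates the study conditions, not any real patient. Its
default configuration is fixed once: cohort mix and per-cohort category
marginals are transcribed from the published original-snapshot tables
(SUEP 1,697 / POP 2,346 / HAP 519); quarter/year are drawn from the
per-cohort joint marginal and the diagnosis date uniformly within the drawn
quarter (drawing the date first and deriving the quarter would contradict
the strongly non-uniform quarter marginals); the most severe disease phase
is drawn per cohort and expanded cumulatively into the three phase flags,
with hospitalization ⇔ not mild; intensive care, ventilation and
in-hospital death follow logistic models with stated coefficients
(death: intercept −3.3, age-over-59 log-OR ln 3 by default — a plausible
clinical magnitude, configurable, and set to ln 4 in the coverage tests);
per-cohort missingness rates for patient status and ventilation match the
published missing fractions. Structural rules are then enforced exactly:
POP contains survivors only and has complete follow-up, HAP is 100 %
hospitalized, follow-up sub-variables are n/a iff no follow-up exists.

What the generator does **not** emulate: real cross-variable dependence
beyond the stated deterministic links and logistic models (e.g. no
age–severity gradient in recruitment, no site effects, no longitudinal
trajectories), non-stationary recruitment intensity, or the real joint
distribution of the key variables. Consequently, passing tests demonstrate
correctness of the *procedure* (guarantees, decisions, estimators) and
qualitative behavior of the *bias* (attenuation with size, rare-stratum
sensitivity) — they do not reproduce the published data-dependent numbers
(maximum published fraction, specific P-values, specific OR deviations),
which require the restricted registry.

One measured caveat: the average re-identification risk of the *released*
data does not fall monotonically along this synthetic stream. The
advancing calendar keeps introducing fresh quarter/year key tuples, i.e.
new classes near size k, which can nudge the record-weighted average up
between snapshots. The robust hiding-in-the-crowd facts — released average
≤ original average at every snapshot, maximum ≤ 1/k — are what the tests
assert.

## Problem sizes and numerical choices

Default analysis stream: n = 4,562 (the reference snapshot size), step 250,
seed 7. Test suites use n = 2,000–50,000 where the property dictates
(50,000 for 2-percentage-point marginal checks, 20,000 for exact structural
rules, 100 × 10,000 replicates for CI coverage). Probability vectors are
validated to sum to 1 within 1e-6; distribution sums within 1e-8 in the
distance function. Diagnosis-date ties are broken by case id, making growth
prefixes a deterministic function of the dataset. All randomness flows from
a single integer seed; pipeline stages derive sub-seeds from
(seed, stage name) so stages can be rerun in isolation.

## Known limitations

- Whole-class suppression is conservative: a single outlying record
  suppresses its k−1 neighbours too.
- The freeze mechanism trades current-reference t-certification for
  non-retraction; audit consumers must read the `frozen` flags.
- Wald CIs undercover for rare outcomes in small strata; the coverage
  property is asserted at n = 10,000 with a prevalent-enough outcome.
- The χ² before/after tests ignore sample overlap (documented above).
- Reference-count expansion reproduces univariate per-cohort tables
  exactly but fabricates the joint structure; it is suitable for
  descriptive arithmetic, not for fitting joint models.
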