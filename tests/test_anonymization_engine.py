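"""Equivalence classes, closeness distances, suppression and increments.

The release decisions are cross-checked against an independent brute-force
reimplementation (plain dict-and-loop, no pandas) on toy and random data.
"""

import numpy as np
import pytest

from pufkit import (
    PrivacyConfig,
    anonymize,
    closeness_distance,
    incremental_release,
    partition_equivalence_classes,
)
from pufkit.anonymize import FROZEN, RELEASED, SUPPRESSED_K, SUPPRESSED_T
from pufkit.errors import ConfigError, DataFormatError
from pufkit.schema import SCHEMA

from conftest import make_dataset


# ---------------------------------------------------------------------------
# independent brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_decisions(dataset, config):
    """Loop-based reimplementation of the per-class release rule."""
    records = dataset.frame.to_dict("records")
    classes = {}
    for record in records:
        key = tuple(record[v] for v in config.key_variables)
        classes.setdefault(key, []).append(record)
    reference = {}
    for variable in config.sensitive_variables:
        categories = SCHEMA[variable].categories
        reference[variable] = {
            c: sum(r[variable] == c for r in records) / len(records)
            for c in categories}
    decisions = {}
    for key, members in classes.items():
        if len(members) < config.k:
            decisions[key] = SUPPRESSED_K
            continue
        status = RELEASED
        for variable in config.sensitive_variables:
            categories = SCHEMA[variable].categories
            p = {c: sum(m[variable] == c for m in members) / len(members)
                 for c in categories}
            q = reference[variable]
            if variable in config.ordinal_sensitive:
                cum, total = 0.0, 0.0
                for c in categories:
                    cum += p[c] - q[c]
                    total += abs(cum)
                distance = total / (len(categories) - 1)
            else:
                distance = 0.5 * sum(abs(p[c] - q[c]) for c in categories)
            if distance > config.t:
                status = SUPPRESSED_T
                break
        decisions[key] = status
    return decisions


def random_toy_dataset(rng, n):
    """Random dataset over a few categories of up to 3 key variables."""
    overrides = []
    for i in range(n):
        overrides.append({
            "case_id": f"r{i:04d}",
            "age_group": rng.choice(["18-39", "40-59", "60-79"]),
            "gender": rng.choice(["male", "female"]),
            "cohort": rng.choice(["SUEP", "POP"]),
            "patient_status_end_acute": rng.choice(
                ["discharged", "dead", "ambulant"]),
            "intensive_care": rng.choice(["yes", "no"]),
        })
    return make_dataset(overrides)


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

class TestPartition:
    def test_empty_dataset_no_classes(self):
        assert partition_equivalence_classes(make_dataset([]), ["gender"]) == []

    def test_identical_tuples_form_one_class(self):
        ds = make_dataset([{} for _ in range(7)])
        classes = partition_equivalence_classes(ds, ["age_group", "gender"])
        assert len(classes) == 1
        assert classes[0].size == 7

    def test_hand_enumerated_sizes(self):
        ds = make_dataset([{"age_group": a} for a in
                           ["18-39", "18-39", "40-59", "40-59", "60-79"]])
        classes = partition_equivalence_classes(ds, ["age_group"])
        assert sorted(c.size for c in classes) == [1, 2, 2]

    def test_classes_partition_records(self, small_synthetic):
        classes = partition_equivalence_classes(
            small_synthetic, ["age_group", "gender", "cohort"])
        ids = [i for c in classes for i in c.member_ids]
        assert len(ids) == len(small_synthetic)
        assert set(ids) == small_synthetic.case_ids

    def test_empty_key_set_rejected(self, small_synthetic):
        with pytest.raises(ConfigError):
            partition_equivalence_classes(small_synthetic, [])


# ---------------------------------------------------------------------------
# closeness distance
# ---------------------------------------------------------------------------

class TestClosenessDistance:
    def test_identical_distributions_zero(self):
        d = {"a": 0.3, "b": 0.7}
        assert closeness_distance(d, d) == 0.0
        assert closeness_distance(d, d, ordinal=True) == 0.0

    def test_nominal_half_l1_by_hand(self):
        got = closeness_distance({"a": 1.0, "b": 0.0}, {"a": 0.5, "b": 0.5})
        assert got == pytest.approx(0.5)

    def test_ordinal_extreme_separation_is_one(self):
        p = {"low": 1.0, "mid": 0.0, "high": 0.0}
        q = {"low": 0.0, "mid": 0.0, "high": 1.0}
        assert closeness_distance(p, q, ordinal=True) == pytest.approx(1.0)

    def test_ordinal_intermediate_by_hand(self):
        # cumulative diffs: |1-0.5|=0.5, |1-1|=0 -> (0.5+0)/2 = 0.25
        p = {"low": 1.0, "mid": 0.0, "high": 0.0}
        q = {"low": 0.5, "mid": 0.5, "high": 0.0}
        assert closeness_distance(p, q, ordinal=True) == pytest.approx(0.25)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = rng.dirichlet(np.ones(4))
            q = rng.dirichlet(np.ones(4))
            dp = dict(zip("abcd", p))
            dq = dict(zip("abcd", q))
            for ordinal in (False, True):
                d1 = closeness_distance(dp, dq, ordinal)
                d2 = closeness_distance(dq, dp, ordinal)
                assert d1 == pytest.approx(d2)
                assert 0 <= d1 <= 1

    def test_mismatched_categories_rejected(self):
        with pytest.raises(DataFormatError):
            closeness_distance({"a": 1.0}, {"b": 1.0})


# ---------------------------------------------------------------------------
# anonymize
# ---------------------------------------------------------------------------

class TestAnonymize:
    def test_below_k_everything_suppressed(self):
        ds = make_dataset([{} for _ in range(10)])
        release = anonymize(ds, PrivacyConfig(k=11))
        assert release.released_ids == frozenset()
        assert all(d.status == SUPPRESSED_K
                   for d in release.class_decisions.values())

    def test_two_homogeneous_classes_fully_released(self):
        overrides = [{"gender": g, "case_id": f"{g}{i}"}
                     for g in ("male", "female") for i in range(11)]
        ds = make_dataset(overrides)
        release = anonymize(ds, PrivacyConfig(k=11))
        assert len(release.released_ids) == 22

    def test_skewed_class_suppressed_by_t(self):
        # one class of 11 all dead; the rest of the data 10% dead overall
        overrides = [{"gender": "male", "patient_status_end_acute": "dead",
                      "case_id": f"m{i}"} for i in range(11)]
        overrides += [{"gender": "female",
                       "patient_status_end_acute": "discharged",
                       "case_id": f"f{i}"} for i in range(99)]
        ds = make_dataset(overrides)
        release = anonymize(ds, PrivacyConfig(k=11, t=0.5))
        decision = next(d for d in release.class_decisions.values()
                        if d.key_tuple[1] == "male")
        assert decision.status == SUPPRESSED_T
        assert decision.offending_variable == "patient_status_end_acute"
        # overall dead fraction 0.1: half-L1 = 0.9
        assert decision.distance == pytest.approx(0.9)

    def test_boundary_distance_equal_t_is_releasable(self):
        # two classes of 11, one all dead, one all discharged -> distance 0.5
        overrides = [{"gender": "male", "patient_status_end_acute": "dead",
                      "case_id": f"m{i}"} for i in range(11)]
        overrides += [{"gender": "female", "case_id": f"f{i}"} for i in range(11)]
        ds = make_dataset(overrides)
        release = anonymize(ds, PrivacyConfig(k=11, t=0.5))
        assert len(release.released_ids) == 22

    @pytest.mark.parametrize("seed,n", [(0, 60), (1, 120), (2, 200)])
    def test_matches_brute_force_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        ds = random_toy_dataset(rng, n)
        config = PrivacyConfig(
            k=4, t=0.3,
            key_variables=("age_group", "gender", "cohort"),
            sensitive_variables=("patient_status_end_acute", "intensive_care"))
        release = anonymize(ds, config)
        expected = brute_force_decisions(ds, config)
        got = {key: d.status for key, d in release.class_decisions.items()}
        assert got == expected

    def test_guarantees_rechecked_by_brute_force(self, small_synthetic):
        config = PrivacyConfig()
        release = anonymize(small_synthetic, config)
        released = release.released_dataset(small_synthetic)
        # k-guarantee among released records
        counts = released.frame.groupby(list(config.key_variables)).size()
        assert (counts >= config.k).all()
        # t-guarantee against the full original distribution
        expected = brute_force_decisions(small_synthetic, config)
        for key, decision in release.class_decisions.items():
            assert (decision.status == RELEASED) == (expected[key] == RELEASED)


# ---------------------------------------------------------------------------
# incremental release
# ---------------------------------------------------------------------------

class TestIncremental:
    def test_no_new_records_identical_release(self, small_synthetic):
        config = PrivacyConfig()
        first = anonymize(small_synthetic, config)
        second = incremental_release(first, small_synthetic, config)
        assert second.released_ids == first.released_ids

    def test_class_growing_past_k_gets_released(self):
        config = PrivacyConfig(k=11)
        stage1 = make_dataset([{"case_id": f"a{i}"} for i in range(10)])
        release1 = anonymize(stage1, config)
        assert release1.released_ids == frozenset()
        stage2 = make_dataset([{"case_id": f"a{i}"} for i in range(11)])
        release2 = incremental_release(release1, stage2, config)
        assert len(release2.released_ids) == 11
        assert release1.released_ids <= release2.released_ids

    def test_class_never_reaching_k_never_released(self):
        config = PrivacyConfig(k=11)
        previous = None
        for n in (3, 6, 9):
            ds = make_dataset(
                [{"case_id": f"a{i}", "gender": "male"} for i in range(n)]
                + [{"case_id": f"b{i}", "gender": "female"} for i in range(11)])
            previous = incremental_release(previous, ds, config)
            assert all(not i.startswith("a") for i in previous.released_ids)

    def test_non_superset_rejected(self, small_synthetic):
        config = PrivacyConfig()
        release = anonymize(small_synthetic, config)
        smaller = small_synthetic.subset(
            list(small_synthetic.case_ids)[: len(small_synthetic) // 2])
        with pytest.raises(DataFormatError):
            incremental_release(release, smaller, config)

    def test_t_drift_freezes_class_without_retraction(self):
        """A class that satisfied t at release time but fails it after the
        reference distribution drifts keeps its released members, is not
        extended, and is flagged as frozen."""
        config = PrivacyConfig(
            k=4, t=0.3, key_variables=("gender",),
            sensitive_variables=("patient_status_end_acute",))
        # stage 1: male class all dead, overall 50% dead -> distance 0.5? no:
        # male 4/4 dead, female 4/4 dead -> both match overall (all dead)
        stage1 = make_dataset(
            [{"case_id": f"m{i}", "gender": "male",
              "patient_status_end_acute": "dead"} for i in range(4)]
            + [{"case_id": f"f{i}", "gender": "female",
                "patient_status_end_acute": "dead"} for i in range(4)])
        release1 = anonymize(stage1, config)
        assert len(release1.released_ids) == 8
        # stage 2: many discharged females arrive; the all-dead male class
        # now sits far from the overall distribution
        stage2 = make_dataset(
            [{"case_id": f"m{i}", "gender": "male",
              "patient_status_end_acute": "dead"} for i in range(5)]
            + [{"case_id": f"f{i}", "gender": "female",
                "patient_status_end_acute": "dead" if i < 4 else "discharged"}
               for i in range(40)])
        release2 = incremental_release(release1, stage2, config)
        male_decision = next(d for d in release2.class_decisions.values()
                             if d.key_tuple == ("male",))
        assert male_decision.status == FROZEN
        assert male_decision.released_ids == frozenset(f"m{i}" for i in range(4))
        assert "m4" not in release2.released_ids
        assert release1.released_ids <= release2.released_ids

    def test_config_change_between_releases_rejected(self, small_synthetic):
        release = anonymize(small_synthetic, PrivacyConfig(k=11))
        with pytest.raises(ConfigError):
            incremental_release(release, small_synthetic, PrivacyConfig(k=5))
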