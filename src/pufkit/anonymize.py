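"""Suppression-based anonymization: k-anonymity plus t-closeness.

A record may be released only if (i) its equivalence class — the group of
records identical on all key variables, with missing labels participating as
ordinary categories — has at least ``k`` members, and (ii) for every
sensitive variable the class's value distribution is within distance ``t``
of that variable's distribution over the *full original input dataset*.
Classes failing either criterion are withheld whole; released records are
never modified (suppression only, no generalization — category coarsening is
fixed upstream in the schema).

Distances: total variation (half L1) for nominal variables; for variables
declared ordinal, the normalized earth-mover distance (mean absolute
cumulative difference scaled so that full separation of the extreme
categories equals 1).  The boundary is inclusive: distance == t is
releasable.

Incremental release: class decisions are recomputed on each cumulative
snapshot; a class once released never has members retracted.  If accruing
data push a previously released class past ``t``, the class is frozen at its
previously released membership and the event is flagged in the audit trail
(status ``frozen``), never silent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortDataset
from .errors import ConfigError, DataFormatError
from .schema import (
    CASE_ID,
    DEFAULT_KEY_VARIABLES,
    DEFAULT_SENSITIVE_VARIABLES,
    SCHEMA,
)

RELEASED = "released"
SUPPRESSED_K = "suppressed_k"
SUPPRESSED_T = "suppressed_t"
FROZEN = "frozen"


@dataclass(frozen=True)
class PrivacyConfig:
    """Privacy parameters: ``k`` for k-anonymity, ``t`` for t-closeness."""

    k: int = 11
    t: float = 0.5
    key_variables: tuple[str, ...] = DEFAULT_KEY_VARIABLES
    sensitive_variables: tuple[str, ...] = DEFAULT_SENSITIVE_VARIABLES
    ordinal_sensitive: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ConfigError(f"k must be >= 2, got {self.k}")
        if not 0.0 <= self.t <= 1.0:
            raise ConfigError(f"t must be in [0, 1], got {self.t}")
        overlap = set(self.key_variables) & set(self.sensitive_variables)
        if overlap:
            raise ConfigError(f"key and sensitive sets overlap: {sorted(overlap)}")
        for v in (*self.key_variables, *self.sensitive_variables):
            if v not in SCHEMA:
                raise ConfigError(f"unknown variable {v!r}")
        if not self.key_variables:
            raise ConfigError("empty key-variable set")


@dataclass(frozen=True)
class EquivalenceClass:
    key_tuple: tuple[str, ...]
    member_ids: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class ClassDecision:
    key_tuple: tuple[str, ...]
    size: int
    status: str
    released_ids: frozenset[str]
    offending_variable: str | None = None
    distance: float | None = None


@dataclass(frozen=True)
class AnonymizedRelease:
    """Outcome of one (possibly incremental) anonymization run."""

    released_ids: frozenset[str]
    suppressed_ids: frozenset[str]
    class_decisions: dict[tuple[str, ...], ClassDecision]
    config: PrivacyConfig
    release_index: int = 0

    @property
    def input_ids(self) -> frozenset[str]:
        return self.released_ids | self.suppressed_ids

    def released_dataset(self, dataset: CohortDataset) -> CohortDataset:
        return dataset.subset(self.released_ids)

    def audit_records(self) -> list[dict]:
        """One JSON-ready entry per class decision."""
        out = []
        for decision in self.class_decisions.values():
            out.append({
                "key_tuple": list(decision.key_tuple),
                "size": decision.size,
                "status": decision.status,
                "n_released": len(decision.released_ids),
                "offending_variable": decision.offending_variable,
                "distance": decision.distance,
            })
        return out


def partition_equivalence_classes(dataset: CohortDataset,
                                  key_variables: Sequence[str],
                                  ) -> list[EquivalenceClass]:
    """Group records by their key tuple (missing labels included)."""
    if not key_variables:
        raise ConfigError("empty key-variable set")
    for v in key_variables:
        if v not in SCHEMA:
            raise DataFormatError(f"unknown key variable {v!r}")
    frame = dataset.frame
    if not len(frame):
        return []
    grouped = frame.groupby(list(key_variables), sort=True, observed=True)[CASE_ID]
    classes = []
    for key, ids in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        classes.append(EquivalenceClass(tuple(map(str, key)), frozenset(ids)))
    return classes


def closeness_distance(class_distribution: Mapping[str, float],
                       reference_distribution: Mapping[str, float],
                       ordinal: bool = False) -> float:
    """Distance between a class distribution and its reference.

    Both mappings must cover the same category set and sum to 1.  Nominal:
    total variation ½·Σ|p−q|.  Ordinal (category order = iteration order of
    ``reference_distribution``): Σ|cumsum(p−q)| / (m−1).
    """
    if set(class_distribution) != set(reference_distribution):
        raise DataFormatError("mismatched category sets")
    order = list(reference_distribution)
    p = np.array([class_distribution[c] for c in order], dtype=float)
    q = np.array([reference_distribution[c] for c in order], dtype=float)
    for name, vec in (("class", p), ("reference", q)):
        if not np.isclose(vec.sum(), 1.0, atol=1e-8):
            raise DataFormatError(f"{name} distribution does not sum to 1")
    if ordinal:
        if len(order) < 2:
            return 0.0
        return float(np.abs(np.cumsum(p - q)).sum() / (len(order) - 1))
    return float(0.5 * np.abs(p - q).sum())


def _class_table(dataset: CohortDataset, config: PrivacyConfig) -> pd.DataFrame:
    """Per-record frame with a class code column."""
    frame = dataset.frame
    codes = frame.groupby(list(config.key_variables), sort=True,
                          observed=True).ngroup()
    return frame.assign(_class=codes)


def _evaluate_classes(dataset: CohortDataset, config: PrivacyConfig,
                      ) -> dict[tuple[str, ...], ClassDecision]:
    """Fresh (non-incremental) per-class decisions on one snapshot."""
    frame = _class_table(dataset, config)
    decisions: dict[tuple[str, ...], ClassDecision] = {}
    if not len(frame):
        return decisions

    groups = frame.groupby("_class", sort=True)
    sizes = groups.size()
    key_of = {
        code: tuple(str(sub.iloc[0][v]) for v in config.key_variables)
        for code, sub in groups
    }
    ids_of = {code: frozenset(sub[CASE_ID]) for code, sub in groups}

    # worst sensitive-variable distance per class, vectorized per variable
    worst = pd.Series(0.0, index=sizes.index)
    worst_var = pd.Series(None, index=sizes.index, dtype=object)
    for variable in config.sensitive_variables:
        categories = list(SCHEMA[variable].categories)
        counts = (frame.groupby(["_class", variable], observed=True).size()
                  .unstack(fill_value=0).reindex(columns=categories, fill_value=0))
        probs = counts.div(counts.sum(axis=1), axis=0)
        ref = (frame[variable].value_counts().reindex(categories, fill_value=0)
               / len(frame))
        diff = probs - ref.to_numpy()
        if variable in config.ordinal_sensitive and len(categories) > 1:
            dist = diff.cumsum(axis=1).abs().sum(axis=1) / (len(categories) - 1)
        else:
            dist = 0.5 * diff.abs().sum(axis=1)
        better = dist > worst
        worst_var[better] = variable
        worst[better] = dist[better]

    for code in sizes.index:
        key, size = key_of[code], int(sizes[code])
        if size < config.k:
            decisions[key] = ClassDecision(key, size, SUPPRESSED_K, frozenset())
        elif worst[code] > config.t:
            decisions[key] = ClassDecision(
                key, size, SUPPRESSED_T, frozenset(),
                offending_variable=worst_var[code], distance=float(worst[code]))
        else:
            decisions[key] = ClassDecision(
                key, size, RELEASED, ids_of[code],
                distance=float(worst[code]))
    return decisions


def _assemble(dataset: CohortDataset, config: PrivacyConfig,
              decisions: dict, release_index: int) -> AnonymizedRelease:
    released = frozenset().union(*(d.released_ids for d in decisions.values())) \
        if decisions else frozenset()
    return AnonymizedRelease(
        released_ids=frozenset(released),
        suppressed_ids=dataset.case_ids - released,
        class_decisions=decisions,
        config=config,
        release_index=release_index,
    )


def anonymize(dataset: CohortDataset, config: PrivacyConfig | None = None,
              ) -> AnonymizedRelease:
    """One-shot anonymization of a single snapshot."""
    config = config or PrivacyConfig()
    return _assemble(dataset, config, _evaluate_classes(dataset, config), 0)


def incremental_release(previous: AnonymizedRelease | None,
                        dataset: CohortDataset,
                        config: PrivacyConfig | None = None,
                        ) -> AnonymizedRelease:
    """Anonymize a grown snapshot without retracting prior releases.

    ``dataset`` must be a superset of the records underlying ``previous``.
    """
    config = config or (previous.config if previous else PrivacyConfig())
    if previous is None:
        return anonymize(dataset, config)
    if previous.config != config:
        raise ConfigError("privacy config changed between incremental releases")
    if not previous.input_ids <= dataset.case_ids:
        raise DataFormatError(
            "incremental release requires a superset of the previous dataset")

    decisions = _evaluate_classes(dataset, config)
    merged: dict[tuple[str, ...], ClassDecision] = {}
    for key, fresh in decisions.items():
        prior = previous.class_decisions.get(key)
        prior_released = prior.released_ids if prior else frozenset()
        if fresh.status == RELEASED:
            merged[key] = fresh
        elif prior_released:
            # class previously released but now failing t: freeze membership
            merged[key] = ClassDecision(
                key, fresh.size, FROZEN, prior_released,
                offending_variable=fresh.offending_variable,
                distance=fresh.distance)
        else:
            merged[key] = fresh
    release = _assemble(dataset, config, merged, previous.release_index + 1)
    assert previous.released_ids <= release.released_ids
    return release


def release_stream(prefixes: Iterable[CohortDataset],
                   config: PrivacyConfig | None = None,
                   ) -> list[AnonymizedRelease]:
    """Chain of incremental releases over nested dataset prefixes."""
    config = config or PrivacyConfig()
    releases: list[AnonymizedRelease] = []
    previous = None
    for prefix in prefixes:
        previous = incremental_release(previous, prefix, config)
        releases.append(previous)
    return releases
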