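"""Variable risk triage: replicability/availability/distinguishability scoring.

Each release variable receives three expert scores in {1, 2, 3} (low /
medium / high risk) along the axes replicability (would an attacker observe
the same value again?), availability (could the value be learned from
external sources?) and distinguishability (how well does it single people
out?).  Variables with a total score above 5 are key variables
(quasi-identifiers) and are protected by k-anonymity; the remaining
variables are sensitive and protected by t-closeness — except those declared
implicitly protected through perfect correlation with an explicitly
protected variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ConfigError, DataFormatError
from . import reference
from .schema import DEFAULT_IMPLICIT_VARIABLES, VARIABLE_NAMES

#: Key-variable threshold: R + A + D strictly greater than this.
KEY_SCORE_THRESHOLD = 5

_VALID_SCORES = {1, 2, 3}


@dataclass(frozen=True)
class VariableRating:
    """Expert risk scores for one variable."""

    variable: str
    replicability: int
    availability: int
    distinguishability: int

    def __post_init__(self) -> None:
        for axis in ("replicability", "availability", "distinguishability"):
            if getattr(self, axis) not in _VALID_SCORES:
                raise ConfigError(
                    f"{self.variable}: {axis} score must be in {{1,2,3}}, "
                    f"got {getattr(self, axis)!r}")


@dataclass(frozen=True)
class TriageResult:
    """Partition of the variable set into key / sensitive / implicit."""

    key_variables: frozenset[str]
    sensitive_variables: frozenset[str]
    implicit_variables: frozenset[str]
    scores: dict[str, int]


def score_variable(rating: VariableRating) -> tuple[int, bool]:
    """Total score and key-variable flag (total > 5)."""
    total = rating.replicability + rating.availability + rating.distinguishability
    return total, total > KEY_SCORE_THRESHOLD


def triage(ratings: Iterable[VariableRating],
           implicit_overrides: Iterable[str] = DEFAULT_IMPLICIT_VARIABLES,
           ) -> TriageResult:
    """Classify every schema variable from its rating.

    Every schema variable must be rated exactly once.  ``implicit_overrides``
    names non-key variables that are only implicitly protected (perfectly
    correlated with an explicitly protected variable); overrides naming key
    variables are ignored, since key variables are already protected.
    """
    ratings = list(ratings)
    seen = [r.variable for r in ratings]
    duplicates = {v for v in seen if seen.count(v) > 1}
    if duplicates:
        raise ConfigError(f"variables rated more than once: {sorted(duplicates)}")
    missing = set(VARIABLE_NAMES) - set(seen)
    if missing:
        raise ConfigError(f"unrated variables: {sorted(missing)}")
    unknown = set(seen) - set(VARIABLE_NAMES)
    if unknown:
        raise ConfigError(f"ratings for unknown variables: {sorted(unknown)}")

    scores = {r.variable: score_variable(r)[0] for r in ratings}
    key = frozenset(v for v, s in scores.items() if s > KEY_SCORE_THRESHOLD)
    implicit = frozenset(implicit_overrides) - key
    sensitive = frozenset(VARIABLE_NAMES) - key - implicit
    return TriageResult(key, sensitive, implicit, scores)


def load_ratings(path: str | Path | None = None) -> list[VariableRating]:
    """Read a ratings CSV (variable, replicability, availability,
    distinguishability); defaults to the packaged expert ratings."""
    if path is None:
        path = reference.ratings_path()
    frame = pd.read_csv(path)
    needed = {"variable", "replicability", "availability", "distinguishability"}
    if not needed <= set(frame.columns):
        raise DataFormatError(f"ratings file lacks columns {sorted(needed - set(frame.columns))}")
    return [
        VariableRating(row["variable"], int(row["replicability"]),
                       int(row["availability"]), int(row["distinguishability"]))
        for _, row in frame.iterrows()
    ]


def default_triage() -> TriageResult:
    """Triage of the packaged ratings with the default implicit overrides."""
    return triage(load_ratings())
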