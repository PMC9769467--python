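"""Category conditions: boolean predicates over schema variables.

A :class:`Condition` selects records whose value for one variable lies in a
stated category set — the building block for regression outcomes/exposures
("patient status is dead", "age group above 59") and for subpopulation
filters ("hospitalized SUEP cases").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .schema import SCHEMA


@dataclass(frozen=True)
class Condition:
    """True iff ``variable``'s value is in ``categories``."""

    variable: str
    categories: frozenset[str]

    def __post_init__(self) -> None:
        if self.variable not in SCHEMA:
            raise ConfigError(f"unknown variable {self.variable!r}")
        unknown = set(self.categories) - set(SCHEMA[self.variable].categories)
        if unknown:
            raise ConfigError(
                f"{self.variable}: categories {sorted(unknown)} not in schema")
        object.__setattr__(self, "categories", frozenset(self.categories))

    def mask(self, frame: pd.DataFrame) -> np.ndarray:
        return frame[self.variable].isin(self.categories).to_numpy()

    def describe(self) -> str:
        return f"{self.variable} in {{{', '.join(sorted(self.categories))}}}"


def cond(variable: str, *categories: str) -> Condition:
    """Shorthand constructor."""
    return Condition(variable, frozenset(categories))


#: Exposure used throughout the worked analyses: age above 59 years.
AGE_OVER_59 = cond("age_group", "60-79", ">=80")
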