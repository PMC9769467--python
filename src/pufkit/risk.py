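"""Prosecutor-model re-identification risk.

An attacker who knows a target's key-variable values and knows the target is
in the dataset picks uniformly among the records of the matching equivalence
class, so a record's re-identification risk is the reciprocal of its class
size.  The profile reports the maximum (1 / smallest class), minimum
(1 / largest class) and the record-weighted average risk, which equals
``n_classes / n_records`` (the mean over records of 1/|class|).  A
class-weighted average (mean of 1/size over classes) is available behind a
flag but is not the default convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import CohortDataset
from .errors import DegenerateStatisticsError
from .anonymize import partition_equivalence_classes
from .schema import DEFAULT_KEY_VARIABLES


@dataclass(frozen=True)
class RiskProfile:
    max_risk: float
    avg_risk: float
    min_risk: float
    n_records: int
    n_classes: int

    def as_percentages(self) -> dict[str, float]:
        """Risks on the percentage scale, rounded to two decimals."""
        return {
            "max": round(100 * self.max_risk, 2),
            "avg": round(100 * self.avg_risk, 2),
            "min": round(100 * self.min_risk, 2),
            "n_records": self.n_records,
            "n_classes": self.n_classes,
        }


def reidentification_risks(dataset: CohortDataset,
                           key_variables: Sequence[str] = DEFAULT_KEY_VARIABLES,
                           class_weighted_average: bool = False) -> RiskProfile:
    """Risk profile of a dataset under the prosecutor model."""
    if not len(dataset):
        raise DegenerateStatisticsError("re-identification risk of an empty dataset")
    sizes = np.array([c.size for c in
                      partition_equivalence_classes(dataset, key_variables)])
    n_records = int(sizes.sum())
    n_classes = len(sizes)
    if class_weighted_average:
        avg = float(np.mean(1.0 / sizes))
    else:
        avg = n_classes / n_records
    return RiskProfile(
        max_risk=float(1.0 / sizes.min()),
        avg_risk=avg,
        min_risk=float(1.0 / sizes.max()),
        n_records=n_records,
        n_classes=n_classes,
    )
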