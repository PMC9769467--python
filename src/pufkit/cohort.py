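"""Cohort dataset container, validation, CSV round-trip, and frequency tables.

A :class:`CohortDataset` wraps a :class:`pandas.DataFrame` holding one row per
case with the 15 release variables, an opaque ``case_id`` and an internal
``diagnosis_date`` used only for ordering growth simulations.  The public CSV
release never carries the date (quarter/year are the released granularity)
nor the case identifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DataFormatError
from .schema import (
    CASE_ID,
    DIAGNOSIS_DATE,
    SCHEMA,
    VARIABLE_NAMES,
)

_ALL_COLUMNS = (CASE_ID, DIAGNOSIS_DATE, *VARIABLE_NAMES)

#: Calendar quarter boundaries (month of first day per quarter).
_QUARTER_OF_MONTH = {m: f"Q{(m - 1) // 3 + 1}" for m in range(1, 13)}


@dataclass(frozen=True)
class Violation:
    """One schema violation found by :func:`validate_dataset`."""

    case_id: str
    variable: str
    value: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.case_id}] {self.variable}={self.value!r}: {self.message}"


class CohortDataset:
    """Immutable-by-convention collection of case records.

    Parameters
    ----------
    frame
        Must contain ``case_id`` and the 15 schema variables; an optional
        ``diagnosis_date`` column (datetime or NaT) is added when absent.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in (CASE_ID, *VARIABLE_NAMES) if c not in frame.columns]
        if missing:
            raise DataFormatError(f"missing mandatory columns: {missing}")
        frame = frame.copy()
        if DIAGNOSIS_DATE not in frame.columns:
            frame[DIAGNOSIS_DATE] = pd.NaT
        frame[DIAGNOSIS_DATE] = pd.to_datetime(frame[DIAGNOSIS_DATE], errors="raise")
        frame[CASE_ID] = frame[CASE_ID].astype(str)
        for name in VARIABLE_NAMES:
            frame[name] = frame[name].astype(str)
        if frame[CASE_ID].duplicated().any():
            dupes = frame.loc[frame[CASE_ID].duplicated(), CASE_ID].tolist()
            raise DataFormatError(f"duplicate case ids: {dupes[:5]}")
        self._frame = frame.loc[:, list(_ALL_COLUMNS)].reset_index(drop=True)

    # -- basic container protocol ------------------------------------------
    def __len__(self) -> int:
        return len(self._frame)

    @property
    def frame(self) -> pd.DataFrame:
        """The underlying table (treat as read-only)."""
        return self._frame

    @property
    def case_ids(self) -> frozenset[str]:
        return frozenset(self._frame[CASE_ID])

    def subset(self, ids: Iterable[str]) -> "CohortDataset":
        ids = set(ids)
        return CohortDataset(self._frame[self._frame[CASE_ID].isin(ids)])

    def ordered(self) -> "CohortDataset":
        """Stable total order by (diagnosis_date, case_id); undated cases last."""
        frame = self._frame.sort_values(
            [DIAGNOSIS_DATE, CASE_ID], na_position="last", kind="mergesort"
        ).reset_index(drop=True)
        return CohortDataset(frame)

    def equals(self, other: "CohortDataset") -> bool:
        a = self._frame.sort_values(CASE_ID, kind="mergesort").reset_index(drop=True)
        b = other._frame.sort_values(CASE_ID, kind="mergesort").reset_index(drop=True)
        return a.equals(b)


def validate_dataset(dataset: CohortDataset) -> list[Violation]:
    """Check every record against the schema; violations are data, not errors.

    Checks category membership for all 15 variables and, where a diagnosis
    date is present, its consistency with the released quarter/year.
    """
    frame = dataset.frame
    violations: list[Violation] = []
    for name in VARIABLE_NAMES:
        allowed = set(SCHEMA[name].categories)
        bad = frame[~frame[name].isin(allowed)]
        violations.extend(
            Violation(row[CASE_ID], name, row[name], "value not in category set")
            for _, row in bad.iterrows()
        )
    dated = frame[frame[DIAGNOSIS_DATE].notna()]
    if len(dated):
        expected_q = dated[DIAGNOSIS_DATE].dt.month.map(_QUARTER_OF_MONTH)
        expected_y = dated[DIAGNOSIS_DATE].dt.year.astype(str)
        for col, expected in (
            ("quarter_first_diagnosis", expected_q),
            ("year_first_diagnosis", expected_y),
        ):
            bad = dated[(dated[col] != expected) & (dated[col] != SCHEMA[col].missing_label)]
            violations.extend(
                Violation(row[CASE_ID], col, row[col],
                          "inconsistent with diagnosis_date")
                for _, row in bad.iterrows()
            )
    return violations


def write_puf_csv(dataset: CohortDataset, path: str | Path, *,
                  include_date: bool = True,
                  include_case_id: bool | None = None) -> None:
    """Write the dataset as CSV (UTF-8, quoted, header row, deterministic order).

    ``include_date=False`` selects the public release projection: the exact
    diagnosis date (and, unless overridden, the case identifier) is omitted;
    quarter/year remain the released time granularity.
    """
    if include_case_id is None:
        include_case_id = include_date
    cols = list(VARIABLE_NAMES)
    if include_date:
        cols = [DIAGNOSIS_DATE, *cols]
    if include_case_id:
        cols = [CASE_ID, *cols]
    frame = dataset.frame.loc[:, cols].copy()
    if include_date:
        frame[DIAGNOSIS_DATE] = frame[DIAGNOSIS_DATE].dt.strftime("%Y-%m-%d")
    frame.to_csv(path, index=False, encoding="utf-8", quoting=1, lineterminator="\n")


def read_puf_csv(path: str | Path) -> CohortDataset:
    """Read a release-format CSV.

    Tolerant-reader contract: unrecognized columns are dropped with a
    warning; empty cells are mapped to the variable's missing label; a file
    with only a header yields an empty dataset.  A missing mandatory column
    or an unparseable row raises :class:`DataFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise DataFormatError(f"no such file: {path}")
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    except Exception as exc:  # malformed CSV structure
        raise DataFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing_cols = [c for c in VARIABLE_NAMES if c not in frame.columns]
    if missing_cols:
        raise DataFormatError(f"{path}: missing mandatory columns {missing_cols}")
    extra = [c for c in frame.columns if c not in _ALL_COLUMNS]
    if extra:
        warnings.warn(f"{path.name}: ignoring unrecognized columns {extra}",
                      stacklevel=2)
        frame = frame.drop(columns=extra)
    for name in VARIABLE_NAMES:
        label = SCHEMA[name].missing_label
        if label is not None:
            frame[name] = frame[name].replace("", label)
    if CASE_ID not in frame.columns:
        frame[CASE_ID] = [f"r{i:06d}" for i in range(len(frame))]
    if DIAGNOSIS_DATE in frame.columns:
        try:
            frame[DIAGNOSIS_DATE] = pd.to_datetime(
                frame[DIAGNOSIS_DATE].replace("", None), format="%Y-%m-%d")
        except ValueError as exc:
            raise DataFormatError(f"{path}: bad diagnosis_date ({exc})") from exc
    return CohortDataset(frame)


def frequency_table(dataset: CohortDataset, variable: str,
                    stratify_by_cohort: bool = False) -> pd.DataFrame:
    """Counts and relative frequencies per category.

    Returns a frame indexed by the variable's categories with ``count`` and
    ``proportion`` columns; with ``stratify_by_cohort`` the columns carry a
    (cohort, statistic) MultiIndex.  Proportions of an empty stratum are NaN.
    """
    if variable not in SCHEMA:
        raise DataFormatError(f"unknown variable {variable!r}")
    categories = list(SCHEMA[variable].categories)
    frame = dataset.frame

    def one(sub: pd.DataFrame) -> pd.DataFrame:
        counts = sub[variable].value_counts().reindex(categories, fill_value=0)
        total = counts.sum()
        props = counts / total if total else counts.astype(float) * np.nan
        return pd.DataFrame({"count": counts.astype(int), "proportion": props})

    if not stratify_by_cohort:
        return one(frame)
    pieces = {c: one(frame[frame["cohort"] == c]) for c in SCHEMA["cohort"].categories}
    return pd.concat(pieces, axis=1)
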