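"""Person-level cohort records and validated CSV input/output.

A cohort is a :class:`pandas.DataFrame` with one row per subject and the
columns in :data:`COHORT_COLUMNS`: a unique ``id``, a binary baseline
``exposure``, the baseline covariates (``sex``, ``age``, ``race``, ``state``,
``period``), the follow-up duration ``time`` in person-years, and the binary
``event`` indicator.  All subjects enter at baseline (time 0); calendar time
appears only through the enrollment-``period`` covariate.  Missing values are
not permitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COHORT_COLUMNS",
    "ANALYSIS_ROW_COLUMNS",
    "CategoryLevels",
    "Subject",
    "CohortSchemaError",
    "CohortValidationError",
    "validate_cohort",
    "read_cohort",
    "write_cohort",
    "subjects_to_cohort",
    "cohort_to_subjects",
    "write_analysis_rows",
]

COHORT_COLUMNS = ("id", "exposure", "sex", "age", "race", "state", "period", "time", "event")

#: Counting-process analysis records: one (start, stop] interval per subject.
ANALYSIS_ROW_COLUMNS = ("id", "start", "stop", "event", "group", "weight")

_DEFAULT_STATES = tuple(f"state{i:02d}" for i in range(1, 15))


@dataclass(frozen=True)
class CategoryLevels:
    """Declared level sets for the categorical covariates.

    The first level of each set is the reference level in design matrices.
    ``state`` is configurable; the default is 14 anonymous levels.
    """

    sex: tuple[str, ...] = ("female", "male")
    race: tuple[str, ...] = ("NH-Black", "NH-White", "Hispanic", "Other")
    state: tuple[str, ...] = _DEFAULT_STATES
    period: tuple[str, ...] = ("2001-2005", "2006-2010", "2011-2015")

    def categorical(self) -> dict[str, tuple[str, ...]]:
        return {"sex": self.sex, "race": self.race, "state": self.state, "period": self.period}


@dataclass
class Subject:
    """One subject's baseline record and follow-up outcome."""

    id: str
    exposure: int
    sex: str
    age: float
    race: str
    state: str
    period: str
    time: float
    event: int


class CohortSchemaError(ValueError):
    """The table's columns do not match the cohort schema."""


class CohortValidationError(ValueError):
    """A row violates a cohort invariant; the message cites the row."""


def _check_schema(df: pd.DataFrame) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"missing required column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if extra:
        raise CohortSchemaError(f"unexpected column(s): {', '.join(extra)}")


def _bad_rows(mask: np.ndarray, row_offset: int) -> str:
    rows = np.flatnonzero(mask)[:5] + row_offset
    return ", ".join(str(r) for r in rows)


def validate_cohort(
    df: pd.DataFrame, levels: CategoryLevels | None = None, *, row_offset: int = 0
) -> pd.DataFrame:
    """Validate a cohort table and return a normalized copy.

    Normalization: columns reordered to :data:`COHORT_COLUMNS`, ``id`` and the
    categorical columns as strings, ``age``/``time`` as float64,
    ``exposure``/``event`` as int64, and a fresh RangeIndex.

    ``row_offset`` is added to positional indices in error messages (CSV
    readers pass 2 so messages cite file line numbers).
    """
    levels = levels or CategoryLevels()
    _check_schema(df)
    out = df.loc[:, list(COHORT_COLUMNS)].reset_index(drop=True)
    n = len(out)
    if n == 0:
        return out.astype(
            {"id": str, "exposure": np.int64, "sex": str, "age": np.float64, "race": str,
             "state": str, "period": str, "time": np.float64, "event": np.int64}
        )

    out["id"] = out["id"].astype(str)
    dup = out["id"].duplicated(keep=False).to_numpy()
    if dup.any():
        raise CohortValidationError(f"duplicate id at row(s) {_bad_rows(dup, row_offset)}")

    for col in ("age", "time"):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna().to_numpy()
        if bad.any():
            raise CohortValidationError(
                f"non-numeric {col} at row(s) {_bad_rows(bad, row_offset)}"
            )
        out[col] = vals.astype(np.float64)
        nonpos = (out[col].to_numpy() <= 0.0)
        if nonpos.any():
            raise CohortValidationError(
                f"{col} must be > 0; violated at row(s) {_bad_rows(nonpos, row_offset)}"
            )

    for col in ("exposure", "event"):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = (vals.isna() | ~vals.isin([0, 1])).to_numpy()
        if bad.any():
            raise CohortValidationError(
                f"{col} must be 0 or 1; violated at row(s) {_bad_rows(bad, row_offset)}"
            )
        out[col] = vals.astype(np.int64)

    for col, lev in levels.categorical().items():
        out[col] = out[col].astype(str)
        bad = ~out[col].isin(lev).to_numpy()
        if bad.any():
            raise CohortValidationError(
                f"{col} value outside declared levels {lev} at row(s) "
                f"{_bad_rows(bad, row_offset)}"
            )
    return out


def read_cohort(path, levels: CategoryLevels | None = None) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Errors cite file line numbers (header = line 1). Row order is preserved.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _check_schema(df)
    return validate_cohort(df, levels, row_offset=2)


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Write a cohort CSV with the documented header and full float precision."""
    _check_schema(cohort)
    cohort.loc[:, list(COHORT_COLUMNS)].to_csv(path, index=False)


def subjects_to_cohort(
    subjects: Iterable[Subject], levels: CategoryLevels | None = None
) -> pd.DataFrame:
    rows = [[getattr(s, c) for c in COHORT_COLUMNS] for s in subjects]
    df = pd.DataFrame(rows, columns=list(COHORT_COLUMNS))
    return validate_cohort(df, levels)


def cohort_to_subjects(cohort: pd.DataFrame) -> list[Subject]:
    return [Subject(*rec) for rec in cohort.loc[:, list(COHORT_COLUMNS)].itertuples(index=False)]


def write_analysis_rows(rows: pd.DataFrame, path) -> None:
    """Export counting-process analysis rows to CSV (debugging aid)."""
    rows.loc[:, list(ANALYSIS_ROW_COLUMNS)].to_csv(path, index=False)
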