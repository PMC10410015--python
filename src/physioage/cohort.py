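"""Cohort table conventions and I/O.

A cohort is a plain :class:`pandas.DataFrame` with one row per individual.
Reserved columns hold identity, demographics and (optionally) survival
follow-up; every other numeric column is treated as a biomarker. Missing
biomarker values are encoded as NaN.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

ID = "id"
AGE = "age"
SEX = "sex"
CYCLE = "cycle"
FOLLOWUP = "followup_time"
DEATH = "death"

RESERVED = (ID, AGE, SEX, CYCLE, FOLLOWUP, DEATH)

AGE_MIN = 12
AGE_MAX = 79


class CohortError(ValueError):
    """Raised when a table violates the cohort contract."""


def biomarker_columns(cohort: pd.DataFrame) -> list[str]:
    """Names of the biomarker columns, in table order."""
    return [c for c in cohort.columns if c not in RESERVED]


def validate_cohort(cohort: pd.DataFrame, require_survival: bool = False) -> None:
    """Check the structural invariants of a cohort table.

    Raises :class:`CohortError` on duplicate ids, out-of-range ages,
    non-numeric biomarker columns, or missing survival columns when
    ``require_survival`` is set.
    """
    if cohort.empty:
        raise CohortError("cohort is empty")
    for col in (ID, AGE, SEX):
        if col not in cohort.columns:
            raise CohortError(f"missing required column {col!r}")
    if cohort[ID].duplicated().any():
        raise CohortError("ids are not unique")
    ages = cohort[AGE]
    if ages.isna().any() or (ages < AGE_MIN).any() or (ages > AGE_MAX).any():
        raise CohortError(f"ages must lie in [{AGE_MIN}, {AGE_MAX}]")
    for col in biomarker_columns(cohort):
        if not pd.api.types.is_numeric_dtype(cohort[col]):
            raise CohortError(f"biomarker column {col!r} is not numeric")
    if require_survival and not {FOLLOWUP, DEATH} <= set(cohort.columns):
        raise CohortError("cohort lacks survival columns")


def read_cohort(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".parquet":
        return pd.read_parquet(path)
    return pd.read_csv(path)


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".parquet":
        cohort.to_parquet(path, index=False)
    else:
        cohort.to_csv(path, index=False)
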