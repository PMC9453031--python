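"""Cohort file schema: typed, range-checked delimited-text I/O.

One row per patient: a unique ``patient_id``, nine territory lesion-count
columns, then clinical columns. Ranges: NIHSS integer 0–42 or missing,
mRS integer 0–6 or missing, volumes ≥ 0 or missing, flags 0/1, etiology
one of the five CCS levels or missing. In strict mode unknown columns and
missing schema columns are rejected; in non-strict mode missing clinical
columns are loaded as all-missing and extra columns are ignored.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from mal_profiler.cohort_stats import ETIOLOGY_LEVELS
from mal_profiler.errors import EmptyInputError, SchemaError
from mal_profiler.synthetic import COHORT_COLUMNS
from mal_profiler.territories import COUNT_COLUMNS

_FLAG_COLUMNS = ("sex", "htn", "dm", "af", "cad", "smoker", "lacunar")
_RANGES = {"nihss": (0, 42), "mrs": (0, 6)}
_VOLUME_COLUMNS = ("dwi_vol_ml", "wmh_vol_ml")


def _check_integer(series: pd.Series, column: str, lo: int, hi: int, allow_missing: bool):
    values = pd.to_numeric(series, errors="coerce")
    bad_parse = series.notna() & values.isna()
    if bad_parse.any():
        row = int(np.flatnonzero(bad_parse)[0])
        raise SchemaError("non-numeric value", row=row, column=column)
    present = values.notna()
    if not allow_missing and not present.all():
        row = int(np.flatnonzero(~present)[0])
        raise SchemaError("missing value not allowed", row=row, column=column)
    vals = values[present]
    bad = (vals < lo) | (vals > hi) | (vals != np.floor(vals))
    if bad.any():
        row = int(np.flatnonzero(present)[np.flatnonzero(bad)[0]])
        raise SchemaError(f"value outside [{lo}, {hi}] or non-integer", row=row, column=column)
    return values


def read_cohort(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Raises :class:`SchemaError` with row and column information on the
    first violation; :class:`EmptyInputError` on an empty file.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={"patient_id": str})
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"cohort file {path} is empty") from None
    return validate_cohort(frame, strict=strict)


def validate_cohort(frame: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Validate (and normalize) an in-memory cohort frame against the schema."""
    frame = frame.copy()
    known = set(COHORT_COLUMNS)
    extra = [c for c in frame.columns if c not in known]
    if strict and extra:
        raise SchemaError(f"unknown columns in strict mode: {extra}", column=extra[0])
    if not strict:
        frame = frame.drop(columns=extra)

    if "patient_id" not in frame.columns:
        raise SchemaError("required column missing", column="patient_id")
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    required = [c for c in missing if c in COUNT_COLUMNS]
    if strict and missing:
        raise SchemaError(f"missing schema columns: {missing}", column=missing[0])
    for col in missing:
        # territory counts default to 0 (missing count means no lesion);
        # clinical columns load as all-missing
        frame[col] = 0 if col in COUNT_COLUMNS else np.nan
    del required

    if frame.empty:
        raise EmptyInputError("cohort has no rows")
    dup = frame["patient_id"].duplicated()
    if dup.any():
        raise SchemaError("duplicate patient_id", row=int(np.flatnonzero(dup)[0]), column="patient_id")

    for col in COUNT_COLUMNS:
        frame[col] = frame[col].fillna(0)
        frame[col] = _check_integer(frame[col], col, 0, 10**6, allow_missing=False).astype(int)
    for col, (lo, hi) in _RANGES.items():
        frame[col] = _check_integer(frame[col], col, lo, hi, allow_missing=True)
    for col in _FLAG_COLUMNS:
        frame[col] = _check_integer(frame[col], col, 0, 1, allow_missing=True)
    for col in _VOLUME_COLUMNS:
        values = pd.to_numeric(frame[col], errors="coerce")
        bad = frame[col].notna() & values.isna()
        if bad.any():
            raise SchemaError("non-numeric volume", row=int(np.flatnonzero(bad)[0]), column=col)
        neg = values.notna() & (values < 0)
        if neg.any():
            raise SchemaError("negative volume", row=int(np.flatnonzero(neg)[0]), column=col)
        frame[col] = values
    et = frame["etiology"]
    bad = et.notna() & ~et.isin(ETIOLOGY_LEVELS)
    if bad.any():
        raise SchemaError(
            f"etiology not one of {ETIOLOGY_LEVELS}",
            row=int(np.flatnonzero(bad)[0]), column="etiology",
        )
    return frame[[c for c in COHORT_COLUMNS] + [c for c in frame.columns if c not in COHORT_COLUMNS]]


def write_cohort(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort (or labelled cohort) frame as CSV, stable formatting."""
    frame.to_csv(path, index=False, float_format="%.6g")
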