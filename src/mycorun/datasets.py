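"""Replicate-level dataset I/O.

Two flat CSV schemas carry all replicate-level data through the pipeline:

* running length (``rl``):
  ``bagasse_pct,wheatbran_pct,beechsawdust_pct,time_days,replicate,rl_cm``
* running rate (``rr``):
  ``bagasse_pct,wheatbran_pct,beechsawdust_pct,replicate,rr_cm_per_day``

Dialect: comma-separated, '.' decimal, UTF-8, mandatory header.  Values are
written with six decimals so a write/read round trip is exact at that
precision.
"""

from __future__ import annotations

from os import PathLike
from typing import Union

import numpy as np
import pandas as pd

__all__ = ["RL_COLUMNS", "RR_COLUMNS", "DatasetError", "read_dataset", "write_dataset", "dataset_columns"]

RL_COLUMNS = ("bagasse_pct", "wheatbran_pct", "beechsawdust_pct", "time_days", "replicate", "rl_cm")
RR_COLUMNS = ("bagasse_pct", "wheatbran_pct", "beechsawdust_pct", "replicate", "rr_cm_per_day")

_COMPONENTS = ("bagasse_pct", "wheatbran_pct", "beechsawdust_pct")

PathArg = Union[str, "PathLike[str]"]


class DatasetError(ValueError):
    """A dataset file violates the schema; the message names row and column."""


def dataset_columns(schema_tag: str) -> tuple[str, ...]:
    if schema_tag == "rl":
        return RL_COLUMNS
    if schema_tag == "rr":
        return RR_COLUMNS
    raise ValueError(f"schema_tag must be 'rl' or 'rr', got {schema_tag!r}")


def _check_range(df: pd.DataFrame, col: str, lo: float, hi: float | None = None) -> None:
    vals = df[col]
    bad = vals < lo if hi is None else (vals < lo) | (vals > hi)
    if bad.any():
        i = int(bad.idxmax())
        raise DatasetError(f"row {i}, column {col!r}: value {vals.loc[i]} out of range")


def validate_dataset(df: pd.DataFrame, schema_tag: str) -> pd.DataFrame:
    """Validate (and coerce dtypes of) a replicate-level dataset in memory."""
    cols = dataset_columns(schema_tag)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DatasetError(f"missing column(s): {missing}")
    df = df.loc[:, list(cols)].copy()
    for c in cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        if coerced.isna().any() and len(df):
            i = int(coerced.isna().idxmax())
            raise DatasetError(f"row {i}, column {c!r}: non-numeric cell {df[c].loc[i]!r}")
        df[c] = coerced.astype(float)
    if len(df) == 0:
        return df
    for c in _COMPONENTS:
        _check_range(df, c, 0, 100)
    _check_range(df, "replicate", 1)
    if schema_tag == "rl":
        _check_range(df, "rl_cm", 0)
        t = df["time_days"]
        bad = (t < 5) | (t > 40) | (t % 5 != 0)
        if bad.any():
            i = int(bad.idxmax())
            raise DatasetError(f"row {i}, column 'time_days': {t.loc[i]} not a multiple of 5 in [5, 40]")
        df["time_days"] = t.astype(float)
    else:
        _check_range(df, "rr_cm_per_day", 0)
    df["replicate"] = df["replicate"].astype(int)
    return df


def read_dataset(path: PathArg, schema_tag: str) -> pd.DataFrame:
    """Read a replicate-level CSV, validating schema and invariants.

    Row order is preserved.  Schema violations raise :class:`DatasetError`
    naming the offending row and column.
    """
    try:
        raw = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise DatasetError(f"{path}: empty file without header") from exc
    return validate_dataset(raw, schema_tag)


def write_dataset(df: pd.DataFrame, path: PathArg, schema_tag: str | None = None) -> None:
    """Write a replicate-level dataset CSV (6-decimal precision, exact round trip)."""
    if schema_tag is None:
        schema_tag = "rl" if "rl_cm" in df.columns else "rr"
    df = validate_dataset(df, schema_tag)
    out = df.copy()
    for c in out.columns:
        if c == "replicate":
            continue
        out[c] = out[c].map(lambda v: np.format_float_positional(round(v, 6), precision=6, trim="-"))
    out.to_csv(path, index=False)
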