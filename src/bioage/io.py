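"""Cohort readers and writers.

Supports CSV/TSV and SAS-XPORT (the distribution format of US national
health surveys, read through :func:`pandas.read_sas`).  Survey variable
names (e.g. ``LBXSCR``) are mapped to the package's canonical column names
via a user-supplied ``column_map``; nothing survey-specific is hard-coded.
Unparseable numeric cells become missing values and are counted, not fatal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SchemaError

__all__ = ["ReadLog", "read_cohort", "write_cohort"]

_MANDATORY = ("ca", "gender")
_NON_NUMERIC = ("subject_id", "gender", "group")


@dataclass
class ReadLog:
    path: str
    n_rows: int
    coerced_cells: dict[str, int] = field(default_factory=dict)

    @property
    def total_coerced(self) -> int:
        return sum(self.coerced_cells.values())


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    if suffix == ".xpt":
        return "sas-xport"
    raise ConfigurationError(
        f"cannot infer format from suffix {suffix!r}; pass format explicitly"
    )


def read_cohort(
    path: str | Path,
    fmt: str | None = None,
    column_map: dict[str, str] | None = None,
    numeric_columns: list[str] | tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, ReadLog]:
    """Read a cohort table and return ``(table, log)``.

    ``column_map`` renames source columns to canonical names
    (``subject_id, ca, gender, group``, biomarkers...).  All columns except
    ``subject_id``/``gender``/``group`` are coerced to numeric (restrict
    with ``numeric_columns``); cells that fail to parse become NaN and are
    counted in the log.  Missing mandatory columns raise a schema error.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file does not exist: {path}")
    fmt = fmt or _infer_format(path)

    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "tsv":
        df = pd.read_csv(path, sep="\t")
    elif fmt == "sas-xport":
        df = pd.read_sas(path, format="xport")
        # byte strings from XPORT -> str
        for col in df.columns:
            if df[col].dtype == object:
                df[col] = df[col].map(
                    lambda v: v.decode() if isinstance(v, bytes) else v
                )
    else:
        raise ConfigurationError(
            f"unknown format {fmt!r}; use 'csv', 'tsv' or 'sas-xport'"
        )

    if column_map:
        df = df.rename(columns=column_map)

    for col in _MANDATORY:
        if col not in df.columns:
            raise SchemaError(
                f"mandatory column {col!r} absent after column mapping"
            )

    to_coerce = (
        list(numeric_columns)
        if numeric_columns is not None
        else [c for c in df.columns if c not in _NON_NUMERIC]
    )
    log = ReadLog(path=str(path), n_rows=len(df))
    for col in to_coerce:
        before = df[col].notna()
        coerced = pd.to_numeric(df[col], errors="coerce")
        n_bad = int((before & coerced.isna()).sum())
        if n_bad:
            log.coerced_cells[col] = n_bad
        df[col] = coerced

    if "subject_id" not in df.columns:
        df.insert(0, "subject_id", [f"row-{i:06d}" for i in range(len(df))])
    df["subject_id"] = df["subject_id"].astype(str)
    return df, log


def write_cohort(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV (the package's interchange format)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
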