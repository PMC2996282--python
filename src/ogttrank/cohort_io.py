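"""Reading and writing cohort and results tables (TSV with header).

The cohort schema: one row per subject with ``subject_id``, ``sex``, ``age``,
``bmi``, the fifteen OGTT concentration columns ``glc_0..glc_120``,
``ins_0..ins_120``, ``cpep_0..cpep_120``, optional IVGTT insulin columns
``ivgtt_ins_m10..ivgtt_ins_60``, and one column per SNP holding minor-allele
counts 0/1/2 (blank = missing genotype). Validation is strict and error
messages carry the offending line number (header = line 1).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .indices import IVGTT_MINUTES, OGTT_MINUTES

__all__ = ["REQUIRED_COLUMNS", "OPTIONAL_COLUMNS", "read_cohort", "write_table", "snp_columns"]

REQUIRED_COLUMNS: tuple[str, ...] = (
    ("subject_id", "sex", "age", "bmi")
    + tuple(f"glc_{m}" for m in OGTT_MINUTES)
    + tuple(f"ins_{m}" for m in OGTT_MINUTES)
    + tuple(f"cpep_{m}" for m in OGTT_MINUTES)
)

OPTIONAL_COLUMNS: tuple[str, ...] = tuple(
    f"ivgtt_ins_{m}" if m >= 0 else f"ivgtt_ins_m{-m}" for m in IVGTT_MINUTES
)

_FLOAT_FORMAT = "%.10g"


def snp_columns(cohort: pd.DataFrame) -> list[str]:
    """Columns that are neither required schema nor optional IVGTT columns."""
    known = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS)
    return [c for c in cohort.columns if c not in known]


def _numeric(frame: pd.DataFrame, col: str, path: str) -> pd.Series:
    raw = frame[col]
    converted = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
    bad = converted.isna() & raw.notna() & (raw != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"{path}: non-numeric value {raw.iloc[row]!r} in column {col!r} "
            f"(line {row + 2})"
        )
    return converted.astype(float)


def read_cohort(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a cohort TSV; returns a typed DataFrame."""
    path = str(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    frame = frame.replace("", np.nan)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    out = pd.DataFrame()
    out["subject_id"] = frame["subject_id"].astype(str)
    dup = out["subject_id"][out["subject_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate subject_id {dup.iloc[0]!r}")
    bad_sex = ~frame["sex"].isin(("female", "male"))
    if bad_sex.any():
        row = int(np.flatnonzero(bad_sex.to_numpy())[0])
        raise ValueError(
            f"{path}: sex must be 'female' or 'male', got {frame['sex'].iloc[row]!r} "
            f"(line {row + 2})"
        )
    out["sex"] = frame["sex"]
    for col in REQUIRED_COLUMNS[2:]:
        out[col] = _numeric(frame, col, path)
    for col in OPTIONAL_COLUMNS:
        if col in frame.columns:
            out[col] = _numeric(frame, col, path)

    known = set(REQUIRED_COLUMNS) | set(OPTIONAL_COLUMNS)
    for col in frame.columns:
        if col in known:
            continue
        vals = _numeric(frame, col, path)  # SNP column
        finite = vals.dropna()
        if not finite.isin((0.0, 1.0, 2.0)).all():
            bad_val = finite[~finite.isin((0.0, 1.0, 2.0))].iloc[0]
            raise ValueError(
                f"{path}: column {col!r} looks like a genotype column but holds "
                f"{bad_val!r}; expected minor-allele counts 0/1/2 or blank"
            )
        out[col] = vals
    return out


def write_table(path: Union[str, Path], table: pd.DataFrame) -> Path:
    """Write any results/cohort table as TSV (blank for missing values)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, na_rep="", float_format=_FLOAT_FORMAT)
    return path
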