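"""Tabular I/O: delimited lipid tables in and out, mg/dL internally.

Tables are comma- or tab-delimited text with one header row.  Header names
are matched case-insensitively after normalising separators to underscores
(``Non HDL-C``, ``non-hdl-c`` and ``NON_HDL_C`` all match).  The required
columns are ``tc``, ``hdl_c`` and ``tg``; everything else (apoB, the five
fraction lipids, age, sex, lpx) is optional and empty cells become missing
values.  A ``units='si'`` flag converts every lipid column from mmol/L (and
apoB from g/L) to the internal mg/dL convention on read, and back on write.

Row-level problems (non-numeric or negative lipid cells) fail fast by
default, naming the row; ``strict=False`` skips and logs the bad rows
instead.
"""

from __future__ import annotations

import logging
import re
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .equations import APOB_MGDL_TO_GL, CHOL_MGDL_TO_MMOLL, TG_MGDL_TO_MMOLL, LipidPanel
from .errors import TableFormatError
from .phenotyping import BQRecord

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "read_table",
    "write_table",
    "panels_from_frame",
    "records_from_frame",
    "frame_from_records",
]

logger = logging.getLogger("vldlc")

REQUIRED_COLUMNS = ("tc", "hdl_c", "tg")
OPTIONAL_COLUMNS = (
    "apob", "vldl_c", "vldl_tg", "ldl_c", "ldl_tg", "hdl_tg", "age", "sex", "lpx",
)

_CHOL_COLUMNS = ("tc", "hdl_c", "vldl_c", "ldl_c")
_TG_COLUMNS = ("tg", "vldl_tg", "ldl_tg", "hdl_tg")

_ALIASES = {
    "total_cholesterol": "tc",
    "cholesterol": "tc",
    "hdl": "hdl_c",
    "hdlc": "hdl_c",
    "triglycerides": "tg",
    "triglyceride": "tg",
    "apo_b": "apob",
    "non_hdl_c": None,  # derived, never read
    "lpx_detected": "lpx",
    "lipoprotein_x": "lpx",
    "vldlc": "vldl_c",
    "vldltg": "vldl_tg",
    "ldlc": "ldl_c",
    "ldltg": "ldl_tg",
    "hdltg": "hdl_tg",
}

_SEX_TO_DISK = {"male": "M", "female": "F", "unknown": "U"}
_SEX_FROM_DISK = {"M": "male", "F": "female", "U": "unknown",
                  "male": "male", "female": "female", "unknown": "unknown"}


def _normalise(name: str) -> str:
    key = re.sub(r"[\s\-./]+", "_", name.strip().lower()).strip("_")
    alias = _ALIASES.get(key, key)
    return alias if alias else key


def _si_factor(column: str) -> Optional[float]:
    if column in _CHOL_COLUMNS:
        return CHOL_MGDL_TO_MMOLL
    if column in _TG_COLUMNS:
        return TG_MGDL_TO_MMOLL
    if column == "apob":
        return APOB_MGDL_TO_GL
    return None


def read_table(path, units: str = "mgdl", strict: bool = True) -> pd.DataFrame:
    """Read a delimited lipid table into a canonical mg/dL DataFrame.

    The delimiter (comma or tab) is sniffed.  Returns a frame whose columns
    are the canonical names; the original row numbers are kept in the index
    so later error messages can point back into the file.
    """
    if units not in ("mgdl", "si"):
        raise TableFormatError(f"units must be 'mgdl' or 'si', got {units!r}")
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [_normalise(c) for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s) {missing}")
    keep = [c for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS if c in df.columns]
    df = df[keep]

    numeric = [c for c in keep if c not in ("sex", "lpx")]
    bad_rows: List[int] = []
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        invalid = coerced.isna() & df[col].notna() & (df[col].astype(str).str.strip() != "")
        negative = coerced < 0
        bad = invalid | negative
        if bad.any():
            rows = list(df.index[bad])
            if strict:
                raise TableFormatError(
                    f"{path}: column {col!r} has non-numeric or negative values "
                    f"at row(s) {rows[:10]}"
                )
            bad_rows.extend(rows)
        df[col] = coerced.where(~negative)
    if bad_rows:
        bad_rows = sorted(set(bad_rows))
        logger.warning("skipping %d malformed row(s): %s", len(bad_rows), bad_rows[:20])
        df = df.drop(index=bad_rows)

    if units == "si":
        n_converted = 0
        for col in numeric:
            f = _si_factor(col)
            if f is not None:
                df[col] = df[col] / f
                n_converted += 1
        logger.info("converted %d column(s) from SI to mg/dL", n_converted)
    if "sex" in df.columns:
        df["sex"] = df["sex"].map(lambda s: _SEX_FROM_DISK.get(str(s).strip(), "unknown"))
    if "lpx" in df.columns:
        df["lpx"] = df["lpx"].fillna(0).astype(float).astype(bool)
    return df


def write_table(df: pd.DataFrame, path, units: str = "mgdl", sep: str = ",") -> None:
    """Write a canonical mg/dL frame back to disk, optionally in SI units."""
    if units not in ("mgdl", "si"):
        raise TableFormatError(f"units must be 'mgdl' or 'si', got {units!r}")
    out = df.copy()
    if units == "si":
        for col in out.columns:
            f = _si_factor(col)
            if f is not None:
                out[col] = out[col] * f
    if "sex" in out.columns:
        out["sex"] = out["sex"].map(lambda s: _SEX_TO_DISK.get(s, "U"))
    if "lpx" in out.columns:
        out["lpx"] = out["lpx"].astype(int)
    out.to_csv(path, sep=sep, index=False)


def panels_from_frame(df: pd.DataFrame) -> List[LipidPanel]:
    """Typed :class:`LipidPanel` per row; missing apoB becomes ``None``."""
    panels = []
    has_apob = "apob" in df.columns
    for i, row in df.iterrows():
        apob = None
        if has_apob and pd.notna(row["apob"]):
            apob = float(row["apob"])
        try:
            panels.append(
                LipidPanel(tc=float(row["tc"]), hdl_c=float(row["hdl_c"]),
                           tg=float(row["tg"]), apob=apob)
            )
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"row {i}: {exc}") from exc
    return panels


def _opt(row: pd.Series, col: str) -> Optional[float]:
    if col in row.index and pd.notna(row[col]):
        return float(row[col])
    return None


def records_from_frame(df: pd.DataFrame) -> List[BQRecord]:
    """Typed :class:`BQRecord` per row (fractions optional)."""
    panels = panels_from_frame(df)
    records = []
    for (i, row), panel in zip(df.iterrows(), panels):
        sex = row["sex"] if "sex" in row.index and pd.notna(row.get("sex")) else "unknown"
        lpx = bool(row["lpx"]) if "lpx" in row.index and pd.notna(row.get("lpx")) else False
        records.append(
            BQRecord(
                panel=panel,
                vldl_c=_opt(row, "vldl_c"),
                vldl_tg=_opt(row, "vldl_tg"),
                ldl_c=_opt(row, "ldl_c"),
                ldl_tg=_opt(row, "ldl_tg"),
                hdl_tg=_opt(row, "hdl_tg"),
                age=_opt(row, "age"),
                sex=sex,
                lpx_detected=lpx,
            )
        )
    return records


def frame_from_records(records: Sequence[BQRecord]) -> pd.DataFrame:
    """Canonical mg/dL frame from BQ records (inverse of records_from_frame)."""
    rows: List[Dict] = []
    for r in records:
        rows.append(
            {
                "tc": r.panel.tc,
                "hdl_c": r.panel.hdl_c,
                "tg": r.panel.tg,
                "apob": r.panel.apob if r.panel.apob is not None else np.nan,
                "vldl_c": r.vldl_c if r.vldl_c is not None else np.nan,
                "vldl_tg": r.vldl_tg if r.vldl_tg is not None else np.nan,
                "ldl_c": r.ldl_c if r.ldl_c is not None else np.nan,
                "ldl_tg": r.ldl_tg if r.ldl_tg is not None else np.nan,
                "hdl_tg": r.hdl_tg if r.hdl_tg is not None else np.nan,
                "age": r.age if r.age is not None else np.nan,
                "sex": r.sex,
                "lpx": r.lpx_detected,
            }
        )
    return pd.DataFrame(rows)
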