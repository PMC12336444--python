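"""Format-exact readers and writers for the pipeline's table dialects.

Two CSV dialects are defined: the patient table (one row per subject,
missing serum encoded as an empty field) and the cell table (one row per
segmented cell).  Round-trips are identity.  Multi-channel images travel as
TIFF with the channel order recorded in metadata.  JSON reports serialize
floats at fixed precision so diffs stay stable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .simulate import CHANNELS

__all__ = [
    "SchemaError", "PATIENT_COLUMNS", "CELL_COLUMNS",
    "read_patient_table", "write_patient_table",
    "read_cell_table", "write_cell_table",
    "read_image_stack", "write_image_stack",
    "write_report", "read_report",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


PATIENT_COLUMNS = ("patient_id", "group", "msln_ctc_count", "ctc_count",
                   "ca125_u_ml", "he4_pmol_l", "age", "figo_stage", "histology")
_PATIENT_INT = ("msln_ctc_count", "ctc_count")
_PATIENT_FLOAT = ("ca125_u_ml", "he4_pmol_l", "age")

CELL_COLUMNS = ("slide_id", "cell_id", "x_um", "y_um", "area_um2",
                "int_dapi", "int_ckmix", "int_cd45", "int_msln")
_CELL_FLOAT = CELL_COLUMNS[2:]
CELL_OPTIONAL = ("true_class", "called_class")


def _check_header(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {', '.join(missing)}")


def _coerce_numeric(df: pd.DataFrame, columns: Sequence[str], path,
                    integer: Sequence[str] = ()) -> None:
    for col in columns:
        raw = df[col]
        out = pd.to_numeric(raw, errors="coerce")
        bad = out.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based + header line
            raise SchemaError(f"{path}: malformed numeric value {raw[bad.idxmax()]!r} "
                              f"in column '{col}' at line {row}")
        df[col] = out.astype("Int64") if col in integer else out


def read_patient_table(path) -> pd.DataFrame:
    """Read a patient CSV; empty serum fields become missing (NaN), never 0."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.replace({"": None})
    _check_header(df, PATIENT_COLUMNS, path)
    _coerce_numeric(df, _PATIENT_INT + _PATIENT_FLOAT, path, integer=_PATIENT_INT)
    if df[list(_PATIENT_INT)].isna().any().any():
        raise SchemaError(f"{path}: count columns must not be missing")
    df[list(_PATIENT_INT)] = df[list(_PATIENT_INT)].astype(int)
    df[list(_PATIENT_FLOAT)] = df[list(_PATIENT_FLOAT)].astype(float)
    for col in ("figo_stage", "histology"):
        df[col] = df[col].fillna("")
    return df[list(PATIENT_COLUMNS)]


def write_patient_table(df: pd.DataFrame, path) -> None:
    _check_header(df, PATIENT_COLUMNS, path)
    df[list(PATIENT_COLUMNS)].to_csv(path, index=False, na_rep="")


def read_cell_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False).replace({"": None})
    _check_header(df, CELL_COLUMNS, path)
    _coerce_numeric(df, _CELL_FLOAT, path)
    cols = list(CELL_COLUMNS) + [c for c in CELL_OPTIONAL if c in df.columns]
    return df[cols]


def write_cell_table(df: pd.DataFrame, path) -> None:
    _check_header(df, CELL_COLUMNS, path)
    cols = list(CELL_COLUMNS) + [c for c in CELL_OPTIONAL if c in df.columns]
    df[cols].to_csv(path, index=False, na_rep="")


def write_image_stack(path, stack: np.ndarray) -> None:
    """Write a (4, H, W) stack as multi-channel TIFF; the channel order
    (DAPI, CKmix, CD45, MSLN) goes into the ImageDescription metadata."""
    stack = np.asarray(stack, dtype=np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack",
                     metadata={"axes": "CYX", "channels": list(CHANNELS)})


def read_image_stack(path) -> np.ndarray:
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] != len(CHANNELS):
        raise SchemaError(f"{path}: expected a ({len(CHANNELS)}, H, W) TIFF stack, "
                          f"got shape {stack.shape}")
    return np.asarray(stack, dtype=float)


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(_round_floats(report), indent=2,
                                     allow_nan=False) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
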