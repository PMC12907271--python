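"""CSV file contracts for the slice and cohort tables.

Both tables are plain delimited text with documented headers (the same
headers the synthetic generator writes).  Reading validates the schema:
a missing required column is a :class:`SchemaError`; malformed rows are
collected — with their 1-based data line numbers — into a
:class:`RowError` rather than silently dropped.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import RowError, SchemaError

SLICE_SCHEMA = {
    "patient_id": "str",
    "slice_index": "int",
    "compartment": "category",
    "area_cm2": "float",
    "mean_density_hu": "float",
    "slice_thickness_mm": "float",
}
COMPARTMENT_VOCAB = {"SM", "IMAT", "VAT", "SAT"}

COHORT_REQUIRED = {
    "patient_id": "str",
    "sex": "category",
    "age_years": "float",
    "height_m": "float",
    "smoking": "category",
    "t_stage": "int",
    "n_stage": "category",
    "tnt": "bool",
    "ocr": "bool",
    "recurrence_time_years": "float",
    "recurrence_event": "bool",
    "death_time_years": "float",
    "death_event": "bool",
    "cancer_death_time_years": "float",
    "cancer_death_event": "bool",
}
VOCABS = {
    "sex": {"male", "female"},
    "smoking": {"never", "ex", "current"},
    "n_stage": {"N0", "N+"},
    "compartment": COMPARTMENT_VOCAB,
}
_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}


def _check_columns(frame: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _coerce(frame: pd.DataFrame, schema: dict, bad: list) -> pd.DataFrame:
    out = frame.copy()
    for col, kind in schema.items():
        if col not in out.columns:
            continue
        if kind in ("float", "int"):
            coerced = pd.to_numeric(out[col], errors="coerce")
            for i in out.index[coerced.isna() & out[col].notna()]:
                bad.append((i + 1, f"non-numeric {col}: {out.at[i, col]!r}"))
            out[col] = coerced
        elif kind == "bool":
            s = out[col].astype(str).str.strip().str.lower().map(_BOOL_MAP)
            for i in out.index[s.isna()]:
                bad.append((i + 1, f"non-boolean {col}: {out.at[i, col]!r}"))
            out[col] = s
        elif kind == "category" and col in VOCABS:
            ok = out[col].isin(VOCABS[col])
            for i in out.index[~ok]:
                bad.append(
                    (i + 1, f"{col} value {out.at[i, col]!r} not in {sorted(VOCABS[col])}")
                )
    return out


def read_slice_table(path) -> pd.DataFrame:
    """Read and validate a per-slice segmentation summary CSV."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    _check_columns(frame, SLICE_SCHEMA, path)
    bad: list[tuple[int, str]] = []
    out = _coerce(frame, SLICE_SCHEMA, bad)
    for i in out.index:
        area = out.at[i, "area_cm2"]
        thick = out.at[i, "slice_thickness_mm"]
        if pd.notna(area) and area < 0:
            bad.append((i + 1, f"negative area_cm2: {area}"))
        if pd.notna(thick) and thick <= 0:
            bad.append((i + 1, f"non-positive slice_thickness_mm: {thick}"))
    dup = out.duplicated(subset=["patient_id", "slice_index", "compartment"])
    for i in out.index[dup]:
        bad.append((i + 1, "duplicate (patient_id, slice_index, compartment)"))
    if bad:
        raise RowError(f"{path}: {len(bad)} malformed row(s)", rows=bad)
    out["slice_index"] = out["slice_index"].astype(int)
    return out


def read_cohort_table(path) -> pd.DataFrame:
    """Read and validate a patient-level cohort CSV."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    _check_columns(frame, COHORT_REQUIRED, path)
    bad: list[tuple[int, str]] = []
    out = _coerce(frame, {**COHORT_REQUIRED,
                          **{c: "float" for c in out_metric_columns(frame)}}, bad)
    for prefix in ("recurrence", "death", "cancer_death"):
        ev, tm = f"{prefix}_event", f"{prefix}_time_years"
        for i in out.index:
            event = out.at[i, ev]
            t = out.at[i, tm]
            if pd.notna(event) and bool(event) and (pd.isna(t) or not np.isfinite(t)):
                bad.append((i + 1, f"{ev} is true but {tm} is missing/non-finite"))
            elif pd.notna(t) and t < 0:
                bad.append((i + 1, f"negative {tm}: {t}"))
    if bad:
        raise RowError(f"{path}: {len(bad)} malformed row(s)", rows=bad)
    out["t_stage"] = out["t_stage"].astype(int)
    return out


def out_metric_columns(frame: pd.DataFrame) -> list[str]:
    from .cutpoints import METRICS

    return [m for m in METRICS if m in frame.columns]


def write_table(frame: pd.DataFrame, path) -> Path:
    """Write a CSV without an index column; full float precision so that
    write/read round-trips are exact."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path
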