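"""Aggregation of per-slice CT segmentation output into patient-level metrics.

The segmentation model emits, for every axial slice in the lumbosacral
(L1-S5) window, the cross-sectional area (cm^2) and mean radiodensity (HU)
of each tissue compartment, plus the slice thickness (mm).  Per patient:

* tissue volume (cm^3) = sum over slices of area x thickness / 10
  (thickness converted mm -> cm);
* tissue density (HU)  = unweighted arithmetic mean of the per-slice mean
  densities (not thickness-weighted — external scans with mixed 1-5 mm
  thickness are averaged the same way);
* volume index (cm^3/m^2) = volume / height^2, for between-patient
  comparability.

Anatomical windowing to L1-S5 is the segmentation model's job; the input
table is assumed pre-windowed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AggregationError, ValidationError

#: compartments entering the skeletal muscle score
SCORE_COMPARTMENTS = ("SM", "IMAT")


@dataclass(frozen=True)
class BodyComposition:
    """Patient-level aggregate of the slice stack (volumes in cm^3, HU)."""

    sm_volume: float
    imat_volume: float
    sm_density: float
    imat_density: float
    n_slices: int


@dataclass(frozen=True)
class IndexedBodyComposition:
    """Height-normalised metrics: volume indices in cm^3/m^2, densities HU."""

    sm_volume_index: float
    imat_volume_index: float
    sm_density: float
    imat_density: float


def _aggregate_compartment(
    comp: pd.DataFrame, name: str, zero_area_in_density: bool, thickness_weighted: bool
) -> tuple[float, float, int]:
    area = comp["area_cm2"].to_numpy(dtype=float)
    thick = comp["slice_thickness_mm"].to_numpy(dtype=float)
    dens = comp["mean_density_hu"].to_numpy(dtype=float)
    if np.any(area < 0):
        raise ValidationError(f"negative {name} area in slice table")
    if np.any(thick <= 0):
        raise ValidationError(f"non-positive slice thickness in {name} slices")
    if not (np.all(np.isfinite(area)) and np.all(np.isfinite(dens))):
        raise ValidationError(f"non-finite {name} slice values")
    volume = float(np.sum(area * thick / 10.0))
    keep = np.ones_like(area, dtype=bool) if zero_area_in_density else area > 0
    if not keep.any():
        raise AggregationError(f"no {name} slices with tissue for density average")
    if thickness_weighted:
        density = float(np.average(dens[keep], weights=thick[keep]))
    else:
        density = float(np.mean(dens[keep]))
    return volume, density, len(comp)


def aggregate_slices(
    slices: pd.DataFrame,
    *,
    zero_area_in_density: bool = False,
    thickness_weighted_density: bool = False,
) -> BodyComposition:
    """Aggregate one patient's slice rows into a :class:`BodyComposition`.

    Parameters
    ----------
    slices
        Rows for a single patient with columns ``compartment``,
        ``area_cm2``, ``mean_density_hu``, ``slice_thickness_mm``.
    zero_area_in_density
        Whether slices with zero tissue area contribute their (meaningless)
        mean density to the density average.  Default False: they count
        toward volume (adding 0) but are excluded from the density mean.
    thickness_weighted_density
        Off by default; the published formula is the plain mean over slices.
    """
    if len(slices) == 0:
        raise AggregationError("empty slice set")
    parts = {}
    n_slices = 0
    for name in SCORE_COMPARTMENTS:
        comp = slices[slices["compartment"] == name]
        if len(comp) == 0:
            raise AggregationError(f"missing compartment {name}")
        vol, dens, n = _aggregate_compartment(
            comp, name, zero_area_in_density, thickness_weighted_density
        )
        parts[name] = (vol, dens)
        n_slices = max(n_slices, n)
    return BodyComposition(
        sm_volume=parts["SM"][0],
        imat_volume=parts["IMAT"][0],
        sm_density=parts["SM"][1],
        imat_density=parts["IMAT"][1],
        n_slices=n_slices,
    )


def compute_indices(bc: BodyComposition, height_m: float) -> IndexedBodyComposition:
    """Normalise volumes by height squared (metres)."""
    if height_m is None or not np.isfinite(height_m) or height_m <= 0:
        raise ValidationError(f"height must be a positive number, got {height_m!r}")
    h2 = height_m**2
    return IndexedBodyComposition(
        sm_volume_index=bc.sm_volume / h2,
        imat_volume_index=bc.imat_volume / h2,
        sm_density=bc.sm_density,
        imat_density=bc.imat_density,
    )


def qc_filter(slice_table: pd.DataFrame) -> pd.DataFrame:
    """Per-patient inclusion flags mirroring scan-quality exclusions.

    Patients with a missing score compartment, zero slices, or non-finite
    values are flagged excluded with a machine-readable reason.  Exclusion
    is a flag, never a silent drop.

    Returns a frame with columns ``patient_id``, ``included``, ``reason``.
    """
    rows = []
    for pid, grp in slice_table.groupby("patient_id", sort=True):
        reason = ""
        missing = [c for c in SCORE_COMPARTMENTS if (grp["compartment"] == c).sum() == 0]
        numeric = grp[["area_cm2", "mean_density_hu", "slice_thickness_mm"]].to_numpy(
            dtype=float
        )
        if len(grp) == 0:
            reason = "zero slices"
        elif missing:
            reason = "missing compartment: " + ",".join(missing)
        elif not np.all(np.isfinite(numeric)):
            reason = "non-finite values"
        elif (numeric[:, 0] < 0).any() or (numeric[:, 2] <= 0).any():
            reason = "invalid area or thickness"
        rows.append({"patient_id": pid, "included": reason == "", "reason": reason})
    return pd.DataFrame(rows, columns=["patient_id", "included", "reason"])


def aggregate_cohort(
    slice_table: pd.DataFrame,
    heights: pd.Series,
    **kwargs,
) -> pd.DataFrame:
    """Aggregate every included patient and attach height-normalised indices.

    ``heights`` maps patient_id -> height in metres.  Returns one row per
    included patient with the four score metrics plus raw volumes.
    """
    qc = qc_filter(slice_table)
    included = set(qc.loc[qc["included"], "patient_id"])
    rows = []
    for pid, grp in slice_table.groupby("patient_id", sort=True):
        if pid not in included:
            continue
        bc = aggregate_slices(grp, **kwargs)
        idx = compute_indices(bc, float(heights.loc[pid]))
        rows.append(
            {
                "patient_id": pid,
                "sm_volume_cm3": bc.sm_volume,
                "imat_volume_cm3": bc.imat_volume,
                "sm_volume_index": idx.sm_volume_index,
                "sm_density": idx.sm_density,
                "imat_volume_index": idx.imat_volume_index,
                "imat_density": idx.imat_density,
                "n_slices": bc.n_slices,
            }
        )
    return pd.DataFrame(rows)
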