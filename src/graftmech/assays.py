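"""Biochemical-assay normalizations for tubular tissue constructs.

DNA, glycosaminoglycan (GAG) and hydroxyproline (HYP) contents are
normalized to the sample dry mass; per-construct DNA is obtained by
scaling the mass-normalized DNA by the estimated total construct mass,
itself the product of the measured mass/surface ratio and the nominal
total construct surface (length × circumference, default
15 mm × 1.5π mm).  Construct growth is reported as the day-14
mass/surface ratio over the pre-seeding baseline (1.0 = no change).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["total_surface_mm2", "normalize_assays", "mass_change_ratio"]

CONSTRUCT_LENGTH_MM = 15.0
CONSTRUCT_CIRCUMFERENCE_MM = 1.5 * np.pi


def total_surface_mm2(
    length_mm: float = CONSTRUCT_LENGTH_MM,
    circumference_mm: float = CONSTRUCT_CIRCUMFERENCE_MM,
) -> float:
    """Nominal total construct surface, length × circumference (mm²)."""
    if length_mm <= 0 or circumference_mm <= 0:
        raise ValueError("construct dimensions must be positive")
    return length_mm * circumference_mm


def normalize_assays(
    table: pd.DataFrame,
    length_mm: float = CONSTRUCT_LENGTH_MM,
    circumference_mm: float = CONSTRUCT_CIRCUMFERENCE_MM,
) -> pd.DataFrame:
    """Add per-dry-mass and per-construct columns to an assay table.

    Expects columns ``sample_id, group, dry_mass_mg, surface_mm2`` and
    raw contents in µg among ``dna_ug, gag_ug, hyp_ug`` (any subset).
    Adds ``<analyte>_per_mass_ug_mg``, ``mass_per_surface_mg_mm2``,
    ``total_mass_mg`` and ``dna_per_construct_ug``.
    """
    need = {"dry_mass_mg", "surface_mm2"}
    if not need.issubset(table.columns):
        raise ValueError(f"assay table needs columns {sorted(need)}")
    if (table["dry_mass_mg"] <= 0).any() or (table["surface_mm2"] <= 0).any():
        raise ValueError("masses and surfaces must be positive")
    out = table.copy()
    surface = total_surface_mm2(length_mm, circumference_mm)
    for analyte in ("dna", "gag", "hyp"):
        col = f"{analyte}_ug"
        if col in out.columns:
            out[f"{analyte}_per_mass_ug_mg"] = out[col] / out["dry_mass_mg"]
    out["mass_per_surface_mg_mm2"] = out["dry_mass_mg"] / out["surface_mm2"]
    out["total_mass_mg"] = out["mass_per_surface_mg_mm2"] * surface
    if "dna_per_mass_ug_mg" in out.columns:
        out["dna_per_construct_ug"] = out["dna_per_mass_ug_mg"] * out["total_mass_mg"]
    return out


def mass_change_ratio(
    day14_mass_per_surface: np.ndarray, initial_mass_per_surface: np.ndarray
) -> np.ndarray:
    """Day-14 mass/surface over the pre-seeding baseline (1.0 = no change)."""
    d = np.asarray(day14_mass_per_surface, dtype=float)
    b = np.asarray(initial_mass_per_surface, dtype=float)
    if np.any(b <= 0) or np.any(d <= 0):
        raise ValueError("mass/surface ratios must be positive")
    return d / b
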