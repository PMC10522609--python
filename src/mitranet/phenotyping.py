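"""Derived cardiac indices and study-arm assignment.

Raw inputs are per-animal echocardiographic dimensions (mm), heart rate and
necropsy organ weights.  Derived quantities: biplane-ellipsoid LV volumes,
stroke volume, cardiac output, ejection fraction, cube-law LV mass and
organ-weight-to-tibial-length ratios.  Animals are assigned to arms by
surgery type and the terminal ejection-fraction cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ellipsoid_volume",
    "stroke_volume",
    "cardiac_output",
    "ejection_fraction",
    "devereux_mass",
    "organ_ratio",
    "assign_group",
    "derive_phenotypes",
    "assign_groups",
]

#: Myocardial density constant for the cube-law LV mass estimate (mg/mm^3
#: scale for rodent echo).  Exposed so callers can override.
DEFAULT_MASS_CONSTANT = 1.053

#: Terminal ejection-fraction cutoff (%) separating decompensated failure
#: from compensated hypertrophy among banded survivors.
DEFAULT_EF_CUTOFF = 30.0

GROUP_SHAM = "Sham"
GROUP_LVH = "AB_LVH"
GROUP_HF = "AB_HF"
GROUP_EXCLUDED = "excluded"


def ellipsoid_volume(long_axis: float, transverse_diameter: float,
                     second_diameter: float | None = None) -> float:
    """LV cavity volume (µl) from the ellipsoid model, V = (π/6)·L·D².

    With ``second_diameter`` given, the two-diameter form
    V = (π/6)·L·D1·D2 is used instead.  1 mm³ ≡ 1 µl.
    """
    if long_axis <= 0 or transverse_diameter <= 0:
        raise ValueError("axis lengths must be positive")
    d2 = transverse_diameter if second_diameter is None else second_diameter
    if d2 <= 0:
        raise ValueError("axis lengths must be positive")
    return (math.pi / 6.0) * long_axis * transverse_diameter * d2


def stroke_volume(lvedv: float, lvesv: float) -> float:
    """SV (µl) = LVEDV − LVESV.  Negative values are flagged, not clamped."""
    if lvedv < 0 or lvesv < 0:
        raise ValueError("volumes must be non-negative")
    sv = lvedv - lvesv
    if sv < 0:
        logger.warning("negative stroke volume (%g µl): LVESV exceeds LVEDV", sv)
    return sv


def cardiac_output(sv_ul: float, heart_rate: float) -> float:
    """CO (ml/min) = SV (µl) × HR (beats/min) / 1000."""
    if heart_rate <= 0:
        raise ValueError("heart rate must be positive")
    return sv_ul * heart_rate / 1000.0


def ejection_fraction(lvedv: float, lvesv: float) -> float:
    """EF (%) = 100 × (LVEDV − LVESV) / LVEDV."""
    if lvedv <= 0:
        raise ValueError("LVEDV must be positive")
    return 100.0 * (lvedv - lvesv) / lvedv


def devereux_mass(awt_d: float, pwt_d: float, lvedd: float,
                  constant: float = DEFAULT_MASS_CONSTANT) -> float:
    """Cube-law LV mass (mg) from diastolic wall thicknesses and diameter.

    mass = k · [(AWTd + PWTd + LVEDD)³ − LVEDD³], all lengths in mm.
    """
    if awt_d < 0 or pwt_d < 0 or lvedd <= 0:
        raise ValueError("wall thicknesses must be >= 0 and LVEDD > 0")
    return constant * ((awt_d + pwt_d + lvedd) ** 3 - lvedd**3)


def organ_ratio(weight: float, tibial_length: float) -> float:
    """Organ weight over tibial length, in the caller's declared units."""
    if tibial_length <= 0:
        raise ValueError("tibial length must be positive")
    if weight < 0:
        raise ValueError("weight must be non-negative")
    return weight / tibial_length


def assign_group(surgery: str, survived_followup: bool,
                 week12_ef: float | None,
                 ef_cutoff: float = DEFAULT_EF_CUTOFF) -> str:
    """Assign a study-arm label from surgery, survival and terminal EF.

    Sham surgery dominates; banded survivors split strictly at
    EF < ``ef_cutoff`` into the failure arm.  Non-survivors and banded
    survivors with missing terminal EF are excluded.
    """
    if surgery not in ("sham", "AB"):
        raise ValueError(f"unknown surgery {surgery!r}")
    if not survived_followup:
        return GROUP_EXCLUDED
    if surgery == "sham":
        return GROUP_SHAM
    if week12_ef is None or (isinstance(week12_ef, float) and math.isnan(week12_ef)):
        logger.warning("banded survivor with missing terminal EF -> excluded")
        return GROUP_EXCLUDED
    return GROUP_HF if week12_ef < ef_cutoff else GROUP_LVH


@dataclass(frozen=True)
class PhenotypeResult:
    """Derived indices for one animal at one timepoint."""

    animal_id: str
    timepoint: int
    lvedv_ul: float
    lvesv_ul: float
    sv_ul: float
    co_ml_min: float
    ef_pct: float
    lv_mass_mg: float
    hw_tl: float | None = None  # g/mm
    lw_tl: float | None = None  # g/mm
    group_label: str | None = None


_ECHO_COLUMNS = [
    "animal_id", "timepoint", "heart_rate", "AWTd", "AWTs", "PWTd", "PWTs",
    "LVEDD", "LVESD", "long_axis_d", "long_axis_s",
]


def derive_phenotypes(echo: pd.DataFrame,
                      mass_constant: float = DEFAULT_MASS_CONSTANT) -> pd.DataFrame:
    """Add derived columns to a per-animal-per-timepoint measurement table.

    Required columns: ``animal_id, timepoint, heart_rate, AWTd, PWTd, LVEDD,
    LVESD, long_axis_d, long_axis_s``.  Optional necropsy columns
    ``heart_weight, lung_weight, tibial_length`` (g, g, mm) yield the
    HW/TL and LW/TL ratios (g/mm).
    """
    missing = [c for c in _ECHO_COLUMNS if c not in echo.columns and c not in ("AWTs", "PWTs")]
    if missing:
        raise ValueError(f"echo table missing columns: {missing}")
    out = echo.copy()
    out["LVEDV"] = [
        ellipsoid_volume(r.long_axis_d, r.LVEDD) for r in out.itertuples()
    ]
    out["LVESV"] = [
        ellipsoid_volume(r.long_axis_s, r.LVESD) for r in out.itertuples()
    ]
    out["SV"] = out["LVEDV"] - out["LVESV"]
    out["CO"] = [cardiac_output(r.SV, r.heart_rate) for r in out.itertuples()]
    out["EF"] = [ejection_fraction(r.LVEDV, r.LVESV) for r in out.itertuples()]
    out["LV_mass_mg"] = [
        devereux_mass(r.AWTd, r.PWTd, r.LVEDD, constant=mass_constant)
        for r in out.itertuples()
    ]
    if {"heart_weight", "lung_weight", "tibial_length"} <= set(out.columns):
        out["HW_TL_g_per_mm"] = [
            organ_ratio(r.heart_weight, r.tibial_length) for r in out.itertuples()
        ]
        out["LW_TL_g_per_mm"] = [
            organ_ratio(r.lung_weight, r.tibial_length) for r in out.itertuples()
        ]
    return out


def assign_groups(phenotypes: pd.DataFrame, terminal_week: int = 12,
                  ef_cutoff: float = DEFAULT_EF_CUTOFF) -> pd.DataFrame:
    """Per-animal arm assignment from the terminal-timepoint EF.

    Requires ``surgery`` and ``survived`` columns (survived defaults to
    True when absent).  Returns one row per animal: ``animal_id, surgery,
    week12_EF, group_label``.
    """
    if "surgery" not in phenotypes.columns:
        raise ValueError("phenotype table needs a 'surgery' column")
    rows = []
    for animal_id, sub in phenotypes.groupby("animal_id", sort=False):
        surgery = sub["surgery"].iloc[0]
        survived = bool(sub["survived"].iloc[0]) if "survived" in sub.columns else True
        terminal = sub[sub["timepoint"] == terminal_week]
        ef = float(terminal["EF"].iloc[0]) if len(terminal) else None
        rows.append({
            "animal_id": animal_id,
            "surgery": surgery,
            "week12_EF": ef,
            "group_label": assign_group(surgery, survived, ef, ef_cutoff=ef_cutoff),
        })
    return pd.DataFrame(rows)
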