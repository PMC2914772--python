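"""Subject-level biometric and ventricular derived quantities.

Covers the arithmetic from raw measurements to the reported indices:

* body surface area (DuBois), body mass index;
* stroke volume and ejection fraction from end-diastolic / end-systolic
  volumes;
* BSA-indexed measures (value / BSA);
* the left-ventricular remodelling index LVRI = LV mass / LV end-diastolic
  volume (g/ml, ~1.03 in healthy hearts);
* the epicardial-fat ratios EAT/LVM and indexed-EAT/LVRI;
* late-gadolinium-enhancement extent as a percentage of LV mass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "IndexValidationError",
    "dubois_bsa",
    "bmi",
    "height_from_bmi",
    "ejection_fraction",
    "stroke_volume",
    "lvri",
    "eat_ratios",
    "lge_extent",
    "index_to_bsa",
    "derive_indices",
    "DerivedIndices",
]


class IndexValidationError(ValueError):
    """An input violates the domain of a derived-index formula."""


def dubois_bsa(weight_kg: float, height_cm: float) -> float:
    """Body surface area in m² by the DuBois formula.

    BSA = 0.007184 × weight(kg)^0.425 × height(cm)^0.725
    """
    if weight_kg <= 0 or height_cm <= 0:
        raise IndexValidationError(
            f"weight and height must be positive, got {weight_kg} kg / {height_cm} cm"
        )
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index, weight(kg) / height(m)²."""
    if weight_kg <= 0 or height_cm <= 0:
        raise IndexValidationError(
            f"weight and height must be positive, got {weight_kg} kg / {height_cm} cm"
        )
    return weight_kg / (height_cm / 100.0) ** 2


def height_from_bmi(weight_kg: float, bmi_kg_per_m2: float) -> float:
    """Invert BMI for height in cm: height = 100·sqrt(weight / BMI)."""
    if weight_kg <= 0 or bmi_kg_per_m2 <= 0:
        raise IndexValidationError("weight and BMI must be positive")
    return 100.0 * math.sqrt(weight_kg / bmi_kg_per_m2)


def ejection_fraction(edv_ml: float, esv_ml: float) -> float:
    """Ejection fraction in percent, 100 × (EDV − ESV)/EDV."""
    if edv_ml <= 0:
        raise IndexValidationError(f"EDV must be positive, got {edv_ml}")
    if esv_ml < 0 or esv_ml > edv_ml:
        raise IndexValidationError(f"need 0 <= ESV <= EDV, got ESV {esv_ml}, EDV {edv_ml}")
    return 100.0 * (edv_ml - esv_ml) / edv_ml


def stroke_volume(edv_ml: float, esv_ml: float) -> float:
    """Stroke volume EDV − ESV in ml."""
    if edv_ml < 0 or esv_ml < 0 or esv_ml > edv_ml:
        raise IndexValidationError(f"need 0 <= ESV <= EDV, got ESV {esv_ml}, EDV {edv_ml}")
    return edv_ml - esv_ml


def lvri(lv_edm_g: float, lv_edv_ml: float) -> float:
    """Left-ventricular remodelling index, mass/volume in g/ml."""
    if lv_edv_ml <= 0:
        raise IndexValidationError(f"LV-EDV must be positive, got {lv_edv_ml}")
    if lv_edm_g < 0:
        raise IndexValidationError(f"LV mass must be non-negative, got {lv_edm_g}")
    return lv_edm_g / lv_edv_ml


def eat_ratios(
    eat_mass_g: float,
    lv_edm_g: float,
    indexed_eat_mass_g_per_m2: float,
    lvri_g_per_ml: float,
) -> tuple[float, float]:
    """The two fat-to-myocardium ratios: (EAT/LVM, indexed-EAT/LVRI)."""
    if lv_edm_g <= 0:
        raise IndexValidationError(f"LV mass must be positive, got {lv_edm_g}")
    if lvri_g_per_ml <= 0:
        raise IndexValidationError(f"LVRI must be positive, got {lvri_g_per_ml}")
    return eat_mass_g / lv_edm_g, indexed_eat_mass_g_per_m2 / lvri_g_per_ml


def lge_extent(lge_mass_g: float, lv_edm_g: float) -> float:
    """Scar extent as a percentage of total LV mass."""
    if lv_edm_g <= 0:
        raise IndexValidationError(f"LV mass must be positive, got {lv_edm_g}")
    if lge_mass_g < 0 or lge_mass_g > lv_edm_g:
        raise IndexValidationError(
            f"need 0 <= LGE mass <= LV mass, got {lge_mass_g} g vs {lv_edm_g} g"
        )
    return 100.0 * lge_mass_g / lv_edm_g


def index_to_bsa(value: float, bsa_m2: float) -> float:
    """Index a measure to body surface area (value per m²)."""
    if bsa_m2 <= 0:
        raise IndexValidationError(f"BSA must be positive, got {bsa_m2}")
    return value / bsa_m2


@dataclass
class DerivedIndices:
    """All derived quantities for one subject."""

    lv_ef_pct: float
    rv_ef_pct: float | None
    lv_sv_ml: float
    rv_sv_ml: float | None
    indexed_eat_mass_g_per_m2: float
    indexed_eat_volume_ml_per_m2: float
    indexed_lv_edm_g_per_m2: float
    lvri_g_per_ml: float
    eat_lvm_ratio: float
    eat_lvri_ratio: float
    lge_extent_pct: float | None


def derive_indices(
    *,
    lv_edv_ml: float,
    lv_esv_ml: float,
    lv_edm_g: float,
    eat_volume_ml: float,
    eat_mass_g: float,
    bsa_m2: float,
    rv_edv_ml: float | None = None,
    rv_esv_ml: float | None = None,
    lge_mass_g: float | None = None,
) -> DerivedIndices:
    """Compute the full set of derived indices from primitive measurements.

    ``None`` inputs propagate to ``None`` outputs (absent, never zero).
    """
    _lvri = lvri(lv_edm_g, lv_edv_ml)
    idx_eat_mass = index_to_bsa(eat_mass_g, bsa_m2)
    ratio_lvm, ratio_lvri = eat_ratios(eat_mass_g, lv_edm_g, idx_eat_mass, _lvri)
    has_rv = rv_edv_ml is not None and rv_esv_ml is not None
    return DerivedIndices(
        lv_ef_pct=ejection_fraction(lv_edv_ml, lv_esv_ml),
        rv_ef_pct=ejection_fraction(rv_edv_ml, rv_esv_ml) if has_rv else None,
        lv_sv_ml=stroke_volume(lv_edv_ml, lv_esv_ml),
        rv_sv_ml=stroke_volume(rv_edv_ml, rv_esv_ml) if has_rv else None,
        indexed_eat_mass_g_per_m2=idx_eat_mass,
        indexed_eat_volume_ml_per_m2=index_to_bsa(eat_volume_ml, bsa_m2),
        indexed_lv_edm_g_per_m2=index_to_bsa(lv_edm_g, bsa_m2),
        lvri_g_per_ml=_lvri,
        eat_lvm_ratio=ratio_lvm,
        eat_lvri_ratio=ratio_lvri,
        lge_extent_pct=lge_extent(lge_mass_g, lv_edm_g) if lge_mass_g is not None else None,
    )
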