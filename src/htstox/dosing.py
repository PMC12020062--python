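"""Dose recalculation between concentration units.

Nanomaterial doses can be expressed as nominal mass per culture-medium
volume (ug/ml), mass delivered per cell growth area (ug/cm2), BET-derived
particle surface area per growth area (cm2/cm2), or an externally measured
cell-delivered dose.  The first two are related by the assay volume and
well growth area; the surface-area unit additionally needs the material's
specific surface area SBET (m2/g) from the Materials sheet.

With a 50 ul assay volume and 0.1 cm2 growth area, 256 ug/ml corresponds to
128 ug/cm2; with SBET = 14 m2/g that is a surface dose of 17.92 cm2/cm2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plate_io import HTSDataset, PlateGeometry

UNIT_UGML = "ug/ml"
UNIT_UGCM2 = "ug/cm2"
UNIT_CM2CM2 = "cm2/cm2"
UNIT_DELIVERED = "delivered_cm2/cm2"

_UNIT_ALIASES = {
    "ugml": UNIT_UGML,
    "ug/ml": UNIT_UGML,
    "µg/ml": UNIT_UGML,
    "ugcm2": UNIT_UGCM2,
    "ug/cm2": UNIT_UGCM2,
    "µg/cm²": UNIT_UGCM2,
    "cm2cm2": UNIT_CM2CM2,
    "cm2/cm2": UNIT_CM2CM2,
    "cm²/cm²": UNIT_CM2CM2,
    "delivered": UNIT_DELIVERED,
    "delivered_cm2/cm2": UNIT_DELIVERED,
}


class DoseConversionError(ValueError):
    pass


def normalize_unit(unit: str) -> str:
    try:
        return _UNIT_ALIASES[unit.strip().lower().replace(" ", "")]
    except KeyError:
        raise DoseConversionError(f"unknown dose unit {unit!r}") from None


@dataclass(frozen=True)
class DoseContext:
    """Inputs for converting one nominal dose.

    sbet_m2g is only required for the surface-area unit; it comes from the
    Materials sheet of the annotation workbook.
    """

    dose_ugml: float
    well_volume_ul: float = 50.0
    growth_area_cm2: float = 0.1
    sbet_m2g: float | None = None

    def __post_init__(self) -> None:
        if self.dose_ugml < 0:
            raise DoseConversionError("dose must be >= 0")
        if self.well_volume_ul <= 0:
            raise DoseConversionError("well_volume_ul must be > 0")
        if self.growth_area_cm2 <= 0:
            raise DoseConversionError("growth_area_cm2 must be > 0")
        if self.sbet_m2g is not None and self.sbet_m2g < 0:
            raise DoseConversionError("sbet_m2g must be >= 0")


def cell_delivered_dose(ctx: DoseContext) -> float:
    """Nominal dose per growth area, in ug/cm2.

    Mass delivered to the well (dose x assay volume, with ul converted to
    ml) divided by the well growth area.
    """
    mass_ug = ctx.dose_ugml * ctx.well_volume_ul / 1000.0
    return mass_ug / ctx.growth_area_cm2


def sbet_effective_dose(ctx: DoseContext) -> float:
    """BET surface-area dose, in cm2 of particle surface per cm2 growth area.

    SBET (m2/g -> cm2/ug via x1e4 / x1e-6) times the delivered mass per
    well, divided by the growth area; equivalently
    ``cell_delivered_dose(ctx) * sbet_m2g / 100``.
    """
    if ctx.sbet_m2g is None:
        raise DoseConversionError(
            "SBET is required for cm2/cm2 doses; add it to the Materials sheet"
        )
    mass_ug = ctx.dose_ugml * ctx.well_volume_ul / 1000.0
    surface_cm2 = ctx.sbet_m2g * 1e4 * mass_ug * 1e-6  # m2/g * g -> m2 -> cm2
    return surface_cm2 / ctx.growth_area_cm2


def _per_material_factor(
    target: str,
    geometry: PlateGeometry,
    material: str,
    sbet: dict[str, float],
    delivered_fraction: dict[str, float] | None,
) -> float:
    """Linear factor from ug/ml to the target unit for one material."""
    f_area = geometry.well_volume_ul / 1000.0 / geometry.growth_area_cm2
    if target == UNIT_UGML:
        return 1.0
    if target == UNIT_UGCM2:
        return f_area
    if target in (UNIT_CM2CM2, UNIT_DELIVERED):
        if material not in sbet:
            raise KeyError(material)
        factor = f_area * sbet[material] / 100.0
        if target == UNIT_DELIVERED:
            if delivered_fraction is None or material not in delivered_fraction:
                raise KeyError(material)
            factor *= delivered_fraction[material]
        return factor
    raise DoseConversionError(f"unknown target unit {target!r}")


def convert_dataset_doses(
    ds: HTSDataset,
    target_unit: str,
    geometry: PlateGeometry | None = None,
    sbet: dict[str, float] | None = None,
    delivered_fraction: dict[str, float] | None = None,
) -> HTSDataset:
    """Rewrite dose_value/dose_unit on every record of a dataset.

    All conversions are linear in dose, so a 2-fold dilution series stays
    2-fold spaced, and converting back recovers the original doses up to
    float rounding.  Controls (dose 0) stay 0 under any unit.  Materials
    lacking the data needed for the requested unit are collected and
    reported together.
    """
    target = normalize_unit(target_unit)
    geometry = geometry or ds.geometry
    sbet = sbet or {}
    out = ds.copy()
    records = out.records

    units = records["dose_unit"].replace("", UNIT_UGML).map(normalize_unit)
    doses = records["dose_value"].astype(float).to_numpy()
    new = np.empty_like(doses)
    missing: set[str] = set()
    factor_cache: dict[tuple[str, str], float] = {}

    for i, (dose, unit, material, role) in enumerate(
        zip(doses, units, records["material_id"], records["role"])
    ):
        if role != "treated" or dose == 0 or not material:
            new[i] = 0.0 if dose == 0 else dose
            if role != "treated":
                new[i] = 0.0
            continue
        try:
            key_src = (unit, material)
            if key_src not in factor_cache:
                factor_cache[key_src] = _per_material_factor(
                    unit, geometry, material, sbet, delivered_fraction
                )
            key_dst = (target, material)
            if key_dst not in factor_cache:
                factor_cache[key_dst] = _per_material_factor(
                    target, geometry, material, sbet, delivered_fraction
                )
        except KeyError:
            missing.add(material)
            continue
        ugml = dose / factor_cache[key_src]
        new[i] = ugml * factor_cache[key_dst]

    if missing:
        raise DoseConversionError(
            f"cannot express doses in {target} for materials missing "
            f"SBET/delivered-dose data: {sorted(missing)}"
        )
    records["dose_value"] = new
    records["dose_unit"] = target
    out.log("convert_dataset_doses", target_unit=target)
    return out


def convert_dose_series(
    doses_ugml: np.ndarray,
    target_unit: str,
    ctx: DoseContext,
) -> np.ndarray:
    """Vectorized single-material conversion from ug/ml (convenience)."""
    target = normalize_unit(target_unit)
    doses = np.asarray(doses_ugml, dtype=float)
    if target == UNIT_UGML:
        return doses.copy()
    out = np.empty_like(doses)
    for i, d in enumerate(doses.ravel()):
        c = DoseContext(d, ctx.well_volume_ul, ctx.growth_area_cm2, ctx.sbet_m2g)
        out.ravel()[i] = (
            cell_delivered_dose(c) if target == UNIT_UGCM2 else sbet_effective_dose(c)
        )
    return out


def delivered_mass_ug(ctx: DoseContext) -> float:
    """Mass per well in ug implied by the ug/cm2 conversion (dimensional check)."""
    return cell_delivered_dose(ctx) * ctx.growth_area_cm2
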