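"""Incubation-vessel configuration for DENIS-style soil-core experiments.

A DENIS vessel holds three repacked soil cores incubated under a He/O2
atmosphere.  Nutrient amendment (KNO3 + glucose) is applied either to a
single core ("1c", 33 % of the surface area) or to all three ("3c", 100 %),
or omitted ("control").  Rates are expressed on a whole-vessel area basis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

#: atom-% 15N of atmospheric N2, the natural-abundance background.
NATURAL_ABUNDANCE_AT_PERCENT = 0.3663

#: 15N/14N isotope ratio of atmospheric N2 (delta = 0 reference).
R15_AIR_N2 = 0.0036765

TREATMENTS = ("1c", "3c", "control")

# whole-vessel application rates and amended-area share per treatment
_TREATMENT_PRESETS: dict[str, dict[str, float]] = {
    "1c": {"n_rate_kg_ha": 25.0, "c_rate_kg_ha": 133.3, "amended_area_fraction": 0.33},
    "3c": {"n_rate_kg_ha": 75.0, "c_rate_kg_ha": 400.0, "amended_area_fraction": 1.0},
    "control": {"n_rate_kg_ha": 0.0, "c_rate_kg_ha": 0.0, "amended_area_fraction": 1.0},
}


@dataclass(frozen=True)
class VesselConfig:
    """Geometry, packing and amendment of one incubation vessel.

    Parameters
    ----------
    vessel_id
        Identifier, e.g. ``"3c-L1"``.
    treatment
        One of ``"1c"``, ``"3c"``, ``"control"``.
    n_cores, core_diameter_mm, core_height_mm
        Core count and dimensions; surface area is ``n_cores * pi (d/2)^2``.
    bulk_density_g_cm3, dry_soil_per_core_g
        Packing density and dry-soil mass per core.
    n_rate_kg_ha, c_rate_kg_ha
        Applied N (as KNO3) and C (as glucose), whole-vessel area basis.
    amended_area_fraction
        Share of the vessel surface that received the amendment, in (0, 1].
    label_at_percent
        atom-% 15N of the applied nitrate: 5.0 for labelled vessels,
        natural abundance otherwise.
    """

    vessel_id: str
    treatment: str
    n_cores: int = 3
    core_diameter_mm: float = 45.0
    core_height_mm: float = 75.0
    bulk_density_g_cm3: float = 0.8
    dry_soil_per_core_g: float = 95.3
    n_rate_kg_ha: float = 0.0
    c_rate_kg_ha: float = 0.0
    amended_area_fraction: float = 1.0
    label_at_percent: float = NATURAL_ABUNDANCE_AT_PERCENT

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}; expected one of {TREATMENTS}")
        if not (0.0 < self.amended_area_fraction <= 1.0):
            raise ValueError("amended_area_fraction must lie in (0, 1]")
        for name in ("n_cores", "core_diameter_mm", "core_height_mm",
                     "bulk_density_g_cm3", "dry_soil_per_core_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_rate_kg_ha < 0 or self.c_rate_kg_ha < 0:
            raise ValueError("application rates must be non-negative")

    @property
    def surface_area_m2(self) -> float:
        """Total soil surface area of the vessel in m2."""
        radius_m = self.core_diameter_mm / 2.0 / 1000.0
        return self.n_cores * math.pi * radius_m**2

    @property
    def dry_soil_total_g(self) -> float:
        return self.n_cores * self.dry_soil_per_core_g

    @property
    def is_labelled(self) -> bool:
        return self.label_at_percent > NATURAL_ABUNDANCE_AT_PERCENT + 1e-6

    @classmethod
    def from_treatment(cls, vessel_id: str, treatment: str, *, labelled: bool = False,
                       **overrides: float) -> "VesselConfig":
        """Build a vessel with the standard rates for a treatment."""
        if treatment not in _TREATMENT_PRESETS:
            raise ValueError(f"unknown treatment {treatment!r}")
        fields = dict(_TREATMENT_PRESETS[treatment])
        fields.update(overrides)
        label = 5.0 if labelled else NATURAL_ABUNDANCE_AT_PERCENT
        return cls(vessel_id=vessel_id, treatment=treatment,
                   label_at_percent=label, **fields)

    def with_label(self, at_percent: float) -> "VesselConfig":
        return replace(self, label_at_percent=at_percent)


def soil_nitrate_stock_kg_ha(vessel: VesselConfig,
                             concentration_mg_n_per_g: float) -> float:
    """Soil NO3--N stock of a vessel expressed per hectare.

    ``concentration_mg_n_per_g`` is the extractable NO3--N content of the
    dry soil (mg N per g dry soil).
    """
    if concentration_mg_n_per_g < 0:
        raise ValueError("concentration must be non-negative")
    mass_kg = vessel.dry_soil_total_g * concentration_mg_n_per_g * 1e-6
    return mass_kg / vessel.surface_area_m2 * 1e4
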