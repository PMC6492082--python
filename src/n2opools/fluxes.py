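"""Gas-flux processing for flow-through soil incubations.

Converts detector concentrations to area-normalised fluxes, subtracts
respiration baselines, integrates cumulative emissions over per-gas windows
and derives the denitrification product ratio N2O/(N2O+N2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .vessels import VesselConfig

log = logging.getLogger(__name__)

R_GAS = 8.314462618  # J mol-1 K-1

ATOMIC_MASS_G_MOL = {"N": 14.0067, "C": 12.011}

#: element reported in the flux and atoms of it per molecule
GAS_ATOMS: dict[str, tuple[str, int]] = {
    "NO": ("N", 1),
    "N2O": ("N", 2),
    "N2": ("N", 2),
    "CO2": ("C", 1),
}

#: integration windows (days after amendment) bracketing each gas's
#: emission peak; used for cumulative-emission summaries.
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "NO": (0.0, 4.0),
    "N2O": (0.0, 10.0),
    "N2": (4.5, 9.5),
    "CO2": (0.0, 10.0),
}

#: constant soil-respiration CO2 flux observed outside the amendment peak,
#: kg C ha-1 h-1; subtracted so CO2 emissions reflect the amendment only.
CO2_BASELINE_KG_HA_H = 0.67

DEFAULT_TEMPERATURE_K = 293.15  # incubation run at 20 degC
DEFAULT_PRESSURE_KPA = 101.325


@dataclass(frozen=True)
class GasFluxSeries:
    """Flux time series for one gas in one vessel.

    ``times`` are elapsed days since amendment (strictly increasing);
    ``fluxes`` are kg N ha-1 d-1 for N gases and kg C ha-1 d-1 for CO2.
    Negative values are only expected after baseline subtraction.
    """

    gas: str
    times: np.ndarray
    fluxes: np.ndarray
    vessel: VesselConfig | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "fluxes", np.asarray(self.fluxes, dtype=float))
        if self.gas not in GAS_ATOMS:
            raise ValueError(f"unknown gas {self.gas!r}")
        if self.times.ndim != 1 or self.times.shape != self.fluxes.shape:
            raise ValueError("times and fluxes must be 1-D arrays of equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.fluxes)):
            raise ValueError("fluxes must be finite")

    def __len__(self) -> int:
        return self.times.size

    @property
    def negative_mask(self) -> np.ndarray:
        """Flags samples driven negative by baseline subtraction."""
        return self.fluxes < 0


@dataclass(frozen=True)
class CumulativeEmission:
    """Trapezoidal integral of a flux series over a window, kg (N|C) ha-1."""

    gas: str
    window_start: float
    window_end: float
    total: float
    vessel: VesselConfig | None = None

    def __post_init__(self) -> None:
        if not self.window_start < self.window_end:
            raise ValueError("window_start must be < window_end")


@dataclass(frozen=True)
class ProductRatioSeries:
    """Denitrification product ratio r = N2O/(N2O+N2) per time.

    ``defined`` flags points where the ratio is meaningful (both fluxes
    non-negative, denominator > 0); elsewhere ``r_n2o`` is NaN — undefined
    points are flagged, never silently filled.
    """

    times: np.ndarray
    r_n2o: np.ndarray
    defined: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "r_n2o", np.asarray(self.r_n2o, dtype=float))
        if self.defined is None:
            object.__setattr__(self, "defined", np.isfinite(self.r_n2o))
        object.__setattr__(self, "defined", np.asarray(self.defined, dtype=bool))
        ok = self.r_n2o[self.defined]
        if ok.size and (np.any(ok < 0) or np.any(ok > 1)):
            raise ValueError("defined product ratios must lie in [0, 1]")


def concentration_to_flux(concentration_ppm: float,
                          flow_rate_ml_min: float,
                          vessel: VesselConfig,
                          gas: str,
                          temperature_k: float = DEFAULT_TEMPERATURE_K,
                          pressure_kpa: float = DEFAULT_PRESSURE_KPA) -> float:
    """Convert a headspace mole fraction to an area flux.

    The vessel outflow (``flow_rate_ml_min``) carries the gas at
    ``concentration_ppm`` (micro-mol per mol).  Ideal-gas molar flow at the
    stated temperature and pressure, times atoms of N (or C for CO2) per
    molecule and the atomic mass, normalised by the vessel surface area,
    gives kg N (or C) ha-1 d-1.  Detector calibration is assumed already
    folded into the concentration.
    """
    if concentration_ppm < 0:
        raise ValueError("concentration must be non-negative")
    if flow_rate_ml_min <= 0:
        raise ValueError("flow_rate must be positive")
    if gas not in GAS_ATOMS:
        raise ValueError(f"unknown gas {gas!r}")
    element, n_atoms = GAS_ATOMS[gas]
    flow_m3_d = flow_rate_ml_min * 1e-6 * 60.0 * 24.0
    molar_flow_mol_d = pressure_kpa * 1e3 * flow_m3_d / (R_GAS * temperature_k)
    mass_kg_d = (concentration_ppm * 1e-6 * molar_flow_mol_d
                 * n_atoms * ATOMIC_MASS_G_MOL[element] * 1e-3)
    return mass_kg_d / vessel.surface_area_m2 * 1e4


def subtract_baseline(series: GasFluxSeries,
                      baseline_kg_ha_h: float) -> GasFluxSeries:
    """Remove a constant baseline flux (given per hour) from a series.

    The baseline is converted to per-day before subtraction.  Resulting
    negative fluxes are retained (conservative mass balance) but logged.
    """
    if baseline_kg_ha_h < 0:
        raise ValueError("baseline must be non-negative")
    adjusted = series.fluxes - 24.0 * baseline_kg_ha_h
    n_neg = int(np.sum(adjusted < 0))
    if n_neg and baseline_kg_ha_h > 0:
        log.warning("baseline subtraction drove %d of %d %s fluxes negative",
                    n_neg, adjusted.size, series.gas)
    return replace(series, fluxes=adjusted)


def cumulative_emission(series: GasFluxSeries,
                        window_start: float,
                        window_end: float) -> CumulativeEmission:
    """Integrate a flux series over [window_start, window_end].

    Linear interpolation between sampling points (trapezoidal rule); the
    window endpoints are interpolated when they fall between samples.  The
    window must lie within the observed time range — no extrapolation.
    """
    t, f = series.times, series.fluxes
    if t.size < 2:
        raise ValueError("need at least two samples to integrate")
    if not window_start < window_end:
        raise ValueError("empty or inverted window")
    if window_start < t[0] - 1e-12 or window_end > t[-1] + 1e-12:
        raise ValueError(
            f"window [{window_start}, {window_end}] outside sampled range "
            f"[{t[0]}, {t[-1]}]")
    inner = t[(t > window_start) & (t < window_end)]
    grid = np.concatenate(([window_start], inner, [window_end]))
    vals = np.interp(grid, t, f)
    total = float(np.trapezoid(vals, grid))
    return CumulativeEmission(gas=series.gas, window_start=window_start,
                              window_end=window_end, total=total,
                              vessel=series.vessel)


def total_denitrification(no: CumulativeEmission,
                          n2o: CumulativeEmission,
                          n2: CumulativeEmission) -> float:
    """Total denitrified N: the sum of all N emitted as NO, N2O and N2."""
    parts = (no, n2o, n2)
    for part, gas in zip(parts, ("NO", "N2O", "N2")):
        if part.gas != gas:
            raise ValueError(f"expected {gas} emission, got {part.gas}")
    vessels = {p.vessel.vessel_id for p in parts if p.vessel is not None}
    if len(vessels) > 1:
        raise ValueError(f"emissions from mixed vessels: {sorted(vessels)}")
    return no.total + n2o.total + n2.total


def product_ratio(n2o: GasFluxSeries, n2: GasFluxSeries) -> ProductRatioSeries:
    """Elementwise N2O/(N2O+N2) on the N2O grid (N2 linearly resampled).

    Points with a non-positive denominator or a negative flux are flagged
    undefined (NaN) rather than filled.  Only the overlap of the two series'
    time ranges is evaluated — no extrapolation.
    """
    lo = max(n2o.times[0], n2.times[0])
    hi = min(n2o.times[-1], n2.times[-1])
    keep = (n2o.times >= lo) & (n2o.times <= hi)
    if not np.any(keep):
        raise ValueError("series have no overlapping time range")
    t = n2o.times[keep]
    f_n2o = n2o.fluxes[keep]
    f_n2 = np.interp(t, n2.times, n2.fluxes)
    denom = f_n2o + f_n2
    defined = (f_n2o >= 0) & (f_n2 >= 0) & (denom > 0)
    r = np.full_like(denom, np.nan)
    np.divide(f_n2o, denom, out=r, where=defined)
    if not np.all(defined):
        log.info("product ratio undefined at %d of %d points",
                 int(np.sum(~defined)), defined.size)
    return ProductRatioSeries(times=t, r_n2o=r, defined=defined)
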