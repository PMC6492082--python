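"""Synthetic DENIS-style incubation experiments with known ground truth.

Generates the full observable set of a 12-vessel, 12-day He/O2 soil-core
incubation: bi-hourly NO/N2O/N2/CO2 flux series (gamma-shaped emission
pulses, delayed N2, CO2 riding a constant respiration baseline),
delta15N-bulk of emitted N2O driven by the two-pool Rayleigh model, and
atom-% 15N series for the 5 at%-labelled vessels, all with configurable
Gaussian noise.  Every generated quantity is also stored noise-free in a
:class:`GroundTruth` so each pipeline stage can be tested by inversion.

Default pulse totals equal the reference cumulative emissions over the
standard per-gas windows; peak timings follow the observed flux shapes.
SP and delta18O channels are phenomenological (interpolated through the
reference measurements) — the model mechanistically describes delta15N
only.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import datasets
from .fluxes import CO2_BASELINE_KG_HA_H, DEFAULT_WINDOWS, GasFluxSeries
from .isotopocules import IsotopocouleRecord
from .rayleigh import (ModelTrajectory, RayleighParameters, fertiliser_pool,
                       simulate_two_pool, soil_pool)
from .tracer import AtomFractionSeries, CubicMixingFunction, SourceContributionSeries, evaluate_mixing
from .vessels import NATURAL_ABUNDANCE_AT_PERCENT, VesselConfig, soil_nitrate_stock_kg_ha

log = logging.getLogger(__name__)

#: default true net isotope effects of the generating model (per mil).
DEFAULT_ETA_PRODUCTION = -30.0
DEFAULT_ETA_REDUCTION = -6.0


@dataclass(frozen=True)
class GasPulse:
    """Gamma-shaped emission pulse normalised to a windowed total.

    The flux profile is a gamma density with mode ``peak_day`` and shape
    ``shape`` (scale = peak/(shape-1)), scaled so its analytic integral
    over ``window`` equals ``total_kg_ha``.
    """

    total_kg_ha: float
    peak_day: float
    shape: float = 4.0
    window: tuple[float, float] = (0.0, 10.0)

    def __post_init__(self) -> None:
        if self.total_kg_ha < 0:
            raise ValueError("pulse total must be non-negative")
        if self.shape <= 1 or self.peak_day <= 0:
            raise ValueError("need shape > 1 and peak_day > 0 for a peaked pulse")

    @property
    def scale(self) -> float:
        return self.peak_day / (self.shape - 1.0)

    def _window_mass(self) -> float:
        lo, hi = self.window
        return float(stats.gamma.cdf(hi, self.shape, scale=self.scale)
                     - stats.gamma.cdf(lo, self.shape, scale=self.scale))

    def flux(self, times: np.ndarray) -> np.ndarray:
        """Noise-free flux (kg ha-1 d-1) on ``times`` (days)."""
        if self.total_kg_ha == 0:
            return np.zeros_like(np.asarray(times, dtype=float))
        dens = stats.gamma.pdf(times, self.shape, scale=self.scale)
        return self.total_kg_ha / self._window_mass() * dens

    def cumulative(self, start: float, end: float) -> float:
        """Analytic integral of the pulse over [start, end]."""
        if self.total_kg_ha == 0:
            return 0.0
        mass = (stats.gamma.cdf(end, self.shape, scale=self.scale)
                - stats.gamma.cdf(start, self.shape, scale=self.scale))
        return self.total_kg_ha / self._window_mass() * float(mass)


def _default_pulses() -> dict[str, dict[str, GasPulse]]:
    cum = datasets.reference_cumulative_emissions()
    peaks = {  # (peak_day, shape) per gas; N2 delayed past the N2O peak
        "NO": (1.0, 3.0), "N2O": (3.5, 4.0), "N2": (5.0, 6.0), "CO2": (3.0, 4.0)}
    out: dict[str, dict[str, GasPulse]] = {}
    for treatment in cum.columns:
        out[treatment] = {}
        for gas in ("NO", "N2O", "N2", "CO2"):
            peak, shape = peaks[gas]
            if treatment == "1c" and gas == "N2O":
                peak = 3.0  # 1c plateaus around days 2-4 rather than peaking late
            if treatment == "control":
                peak = {"NO": 1.5, "N2O": 1.75, "N2": 5.0, "CO2": 3.0}[gas]
            out[treatment][gas] = GasPulse(total_kg_ha=float(cum.loc[gas, treatment]),
                                           peak_day=peak, shape=shape,
                                           window=DEFAULT_WINDOWS[gas])
    return out


def default_vessels() -> tuple[VesselConfig, ...]:
    """12 vessels: 4 per treatment, 2 of 4 labelled in 1c and 3c."""
    vessels = []
    for treatment in ("1c", "3c"):
        for k in range(1, 5):
            vessels.append(VesselConfig.from_treatment(
                f"{treatment}-{k}", treatment, labelled=k <= 2))
    for k in range(1, 5):
        vessels.append(VesselConfig.from_treatment(f"control-{k}", "control"))
    return tuple(vessels)


def default_parameters(treatment: str,
                       eta_production: float = DEFAULT_ETA_PRODUCTION,
                       eta_reduction: float = DEFAULT_ETA_REDUCTION) -> RayleighParameters:
    """True Rayleigh parameters for an amended treatment.

    Pool 1 holds the whole-vessel applied N (25 / 75 kg N ha-1) at 0 per
    mil over the amended volume; pool 2 holds the native soil nitrate
    stock (pre-priming content over the whole vessel) at +10 per mil.
    """
    vessel = VesselConfig.from_treatment(f"{treatment}-proto", treatment)
    pool1 = fertiliser_pool(vessel.n_rate_kg_ha, delta_no3_initial=0.0,
                            volume_fraction=vessel.amended_area_fraction)
    n_soil = soil_nitrate_stock_kg_ha(vessel, datasets.SOIL_NO3_MG_PER_G_PRE_PRIMING)
    pool2 = soil_pool(n_soil)
    return RayleighParameters(eta_production=eta_production,
                              eta_reduction=eta_reduction,
                              pools=(pool1, pool2))


@dataclass(frozen=True)
class SyntheticScenario:
    """Complete configuration of one synthetic experiment."""

    seed: int
    vessels: tuple[VesselConfig, ...] = field(default_factory=default_vessels)
    duration_days: float = 12.0
    flux_interval_hours: float = 2.0
    pulses: dict[str, dict[str, GasPulse]] = field(default_factory=_default_pulses)
    params: dict[str, RayleighParameters] = field(default_factory=lambda: {
        "1c": default_parameters("1c"), "3c": default_parameters("3c")})
    mixing: dict[str, CubicMixingFunction] = field(default_factory=lambda: {
        "1c": datasets.MIXING_1C, "3c": datasets.MIXING_3C})
    noise_flux_rel: float = 0.05
    noise_delta_permil: float = 2.0
    noise_at_percent: float = 0.1
    unlabelled_days: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 9.0, 11.0)
    labelled_days: tuple[float, ...] = (0.0, 0.17, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 11.0)

    def __post_init__(self) -> None:
        for name in ("noise_flux_rel", "noise_delta_permil", "noise_at_percent"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def flux_times(self) -> np.ndarray:
        step = self.flux_interval_hours / 24.0
        n = int(round(self.duration_days / step))
        return np.linspace(0.0, n * step, n + 1)

    def vessel_rng(self, vessel_id: str) -> np.random.Generator:
        """Independent stream per vessel: adding vessels never perturbs others."""
        return np.random.default_rng([self.seed, zlib.crc32(vessel_id.encode())])


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free generating quantities of a scenario."""

    scenario: SyntheticScenario
    fluxes: dict[str, dict[str, GasFluxSeries]]        # treatment -> gas -> series
    cumulative: dict[str, dict[str, float]]            # windowed analytic totals
    trajectories: dict[str, ModelTrajectory]           # amended treatments
    contributions: dict[str, SourceContributionSeries]  # true x1(t) in percent


def generate_fluxes(scenario: SyntheticScenario
                    ) -> tuple[dict[str, dict[str, GasFluxSeries]], GroundTruth]:
    """Per-vessel noisy flux series plus the scenario's ground truth.

    CO2 rides the constant respiration baseline; noise is multiplicative
    Gaussian, clipped at zero.  Pulses whose mass extends materially past
    the incubation window are truncated with a warning.
    """
    t = scenario.flux_times
    baseline = 24.0 * CO2_BASELINE_KG_HA_H

    truth_fluxes: dict[str, dict[str, GasFluxSeries]] = {}
    truth_cum: dict[str, dict[str, float]] = {}
    for treatment, pulses in scenario.pulses.items():
        proto = VesselConfig.from_treatment(f"{treatment}-proto", treatment)
        truth_fluxes[treatment] = {}
        truth_cum[treatment] = {}
        for gas, pulse in pulses.items():
            tail = pulse.cumulative(scenario.duration_days, np.inf)
            if pulse.total_kg_ha > 0 and tail > 0.01 * pulse.total_kg_ha:
                log.warning("%s %s pulse: %.1f%% of its mass lies beyond day %g "
                            "and is truncated", treatment, gas,
                            100 * tail / pulse.total_kg_ha, scenario.duration_days)
            flux = pulse.flux(t)
            if gas == "CO2":
                flux = flux + baseline
            truth_fluxes[treatment][gas] = GasFluxSeries(gas=gas, times=t,
                                                         fluxes=flux, vessel=proto)
            lo, hi = pulse.window
            truth_cum[treatment][gas] = pulse.cumulative(lo, hi)

    trajectories: dict[str, ModelTrajectory] = {}
    contributions: dict[str, SourceContributionSeries] = {}
    for treatment, params in scenario.params.items():
        mixing = scenario.mixing[treatment]
        traj = simulate_two_pool(params,
                                 truth_fluxes[treatment]["N2O"],
                                 truth_fluxes[treatment]["N2"], mixing)
        trajectories[treatment] = traj
        days = np.asarray(scenario.labelled_days)
        contributions[treatment] = SourceContributionSeries(
            times=days, percent_fertiliser=evaluate_mixing(mixing, days),
            treatment=treatment)

    truth = GroundTruth(scenario=scenario, fluxes=truth_fluxes,
                        cumulative=truth_cum, trajectories=trajectories,
                        contributions=contributions)

    observed: dict[str, dict[str, GasFluxSeries]] = {}
    for vessel in scenario.vessels:
        rng = scenario.vessel_rng(vessel.vessel_id)
        observed[vessel.vessel_id] = {}
        for gas in ("NO", "N2O", "N2", "CO2"):
            base = truth_fluxes[vessel.treatment][gas]
            noisy = base.fluxes * (1.0 + scenario.noise_flux_rel * rng.standard_normal(t.size))
            observed[vessel.vessel_id][gas] = GasFluxSeries(
                gas=gas, times=t, fluxes=np.clip(noisy, 0.0, None), vessel=vessel)
    return observed, truth


def generate_isotopes(scenario: SyntheticScenario, truth: GroundTruth
                      ) -> tuple[dict[str, list[IsotopocouleRecord]],
                                 dict[str, AtomFractionSeries]]:
    """Isotope observables: unlabelled isotopocule records, labelled at% series.

    Unlabelled amended vessels sample the two-pool model's delta15N-bulk at
    the unlabelled sampling days (plus noise); SP and delta18O are
    interpolated through the reference measurements (phenomenological, not
    modelled).  Labelled vessels mix the 5 at% fertiliser and
    natural-abundance soil end-members with the true x1(t).
    """
    ref = datasets.reference_isotopocules()
    unlabelled: dict[str, list[IsotopocouleRecord]] = {}
    labelled: dict[str, AtomFractionSeries] = {}
    days_u = np.asarray(scenario.unlabelled_days)
    days_l = np.asarray(scenario.labelled_days)

    for vessel in scenario.vessels:
        rng = scenario.vessel_rng(vessel.vessel_id)
        rng_iso = np.random.default_rng(rng.integers(2**31))
        tr_ref = ref[ref.treatment == vessel.treatment]
        sp_anchor = np.interp(days_u, tr_ref.time_days, tr_ref.sp)
        o18_anchor = np.interp(days_u, tr_ref.time_days, tr_ref.delta_o18)
        if vessel.is_labelled:
            mixing = scenario.mixing[vessel.treatment]
            x1 = np.asarray(evaluate_mixing(mixing, days_l)) / 100.0
            at = (x1 * vessel.label_at_percent
                  + (1.0 - x1) * NATURAL_ABUNDANCE_AT_PERCENT)
            at = at + scenario.noise_at_percent * rng_iso.standard_normal(days_l.size)
            labelled[vessel.vessel_id] = AtomFractionSeries(
                times=days_l, at_percent=at,
                a_fertiliser=vessel.label_at_percent,
                vessel_id=vessel.vessel_id)
            continue
        if vessel.treatment in truth.trajectories:
            traj = truth.trajectories[vessel.treatment]
            bulk = np.interp(days_u, traj.times, traj.delta_bulk_mixed)
        else:  # control: no amendment pool, phenomenological only
            bulk = np.interp(days_u, tr_ref.time_days, tr_ref.delta_bulk)
        noise = scenario.noise_delta_permil
        bulk = bulk + noise * rng_iso.standard_normal(days_u.size)
        sp = sp_anchor + noise * rng_iso.standard_normal(days_u.size)
        o18 = o18_anchor + noise * rng_iso.standard_normal(days_u.size)
        unlabelled[vessel.vessel_id] = [
            IsotopocouleRecord.from_sp(float(d), float(b), float(s), float(o))
            for d, b, s, o in zip(days_u, bulk, sp, o18)]
    return unlabelled, labelled


@dataclass(frozen=True)
class SyntheticExperiment:
    """Bundle of everything one scenario generates."""

    scenario: SyntheticScenario
    fluxes: dict[str, dict[str, GasFluxSeries]]
    truth: GroundTruth
    isotopocules: dict[str, list[IsotopocouleRecord]]
    labelled: dict[str, AtomFractionSeries]


def generate_experiment(scenario: SyntheticScenario) -> SyntheticExperiment:
    """Run both generators and bundle the outputs."""
    fluxes, truth = generate_fluxes(scenario)
    unlabelled, labelled = generate_isotopes(scenario, truth)
    return SyntheticExperiment(scenario=scenario, fluxes=fluxes, truth=truth,
                               isotopocules=unlabelled, labelled=labelled)
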