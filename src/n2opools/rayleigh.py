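"""Closed-system Rayleigh modelling of delta15N in soil-emitted N2O.

The model tracks one or two nitrate pools (fertiliser-derived pool 1 and
native-soil pool 2).  As denitrification consumes a pool's nitrate the
residual substrate enriches along the Rayleigh curve

    delta_S = (delta_S0 + 1000) * f**(eta/1000) - 1000,

with f the unconsumed fraction and eta the net isotope effect (NIE) of
N2O production, defined here as delta_product - delta_substrate, so
*normal* fractionation is negative.  Instantaneously produced N2O takes
delta_N2O-p ~= delta_NO3-residual + eta_production; partial reduction of
N2O to N2 then shifts the surviving (emitted) N2O along a second Rayleigh
curve whose f is the instantaneous product ratio N2O/(N2O+N2).  With two
pools, the tracer-calibrated mixing function x1(t) apportions the N loss
between pools and mixes their emitted signatures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares

from .fluxes import GasFluxSeries, ProductRatioSeries, product_ratio
from .tracer import CubicMixingFunction, evaluate_mixing

log = logging.getLogger(__name__)

#: literature delta15N of native soil nitrate, per mil.
DEFAULT_SOIL_NO3_DELTA = 10.0


class SubstrateExhaustedError(RuntimeError):
    """Cumulative loss reached or exceeded a pool's initial nitrate."""

    def __init__(self, pool: str, time_days: float | None = None):
        self.pool = pool
        self.time_days = time_days
        msg = f"nitrate pool {pool!r} exhausted"
        if time_days is not None:
            msg += f" at day {time_days:.3g}"
        super().__init__(msg)


@dataclass(frozen=True)
class NitrogenPool:
    """One nitrate pool feeding denitrification.

    ``n_no3_initial_kg_ha`` is the NO3--N available to the pool and
    ``delta_no3_initial`` its delta15N (per mil vs air N2) before any
    consumption.  ``volume_fraction`` is the share of the vessel soil the
    pool occupies (0.33 or 1.0 for the amended pool, by treatment).
    """

    name: str
    n_no3_initial_kg_ha: float
    delta_no3_initial: float
    volume_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n_no3_initial_kg_ha <= 0:
            raise ValueError("initial nitrate mass must be positive")
        if not (0.0 < self.volume_fraction <= 1.0):
            raise ValueError("volume_fraction must lie in (0, 1]")
        if self.delta_no3_initial <= -1000.0:
            raise ValueError("delta15N must exceed -1000 per mil")


def fertiliser_pool(n_applied_kg_ha: float,
                    delta_no3_initial: float | None = None,
                    volume_fraction: float = 1.0) -> NitrogenPool:
    """Pool 1: nitrate added with the amendment.

    The fertiliser delta15N is a measurable property of the KNO3 used; when
    not supplied it defaults to 0 per mil with a loud log message.
    """
    if delta_no3_initial is None:
        log.warning("fertiliser delta15N-NO3 not supplied; defaulting to 0 per mil "
                    "- supply the measured value of the applied KNO3 if available")
        delta_no3_initial = 0.0
    return NitrogenPool("pool1_fertiliser", n_applied_kg_ha,
                        delta_no3_initial, volume_fraction)


def soil_pool(n_no3_kg_ha: float,
              delta_no3_initial: float = DEFAULT_SOIL_NO3_DELTA,
              volume_fraction: float = 1.0) -> NitrogenPool:
    """Pool 2: native soil nitrate (literature default +10 per mil)."""
    return NitrogenPool("pool2_soil", n_no3_kg_ha, delta_no3_initial,
                        volume_fraction)


@dataclass(frozen=True)
class RayleighParameters:
    """Net isotope effects and pool definitions of the model.

    ``eta_production`` is the NIE of N2O production from nitrate
    (eta_N2O-NO3) and ``eta_reduction`` the NIE of N2O reduction to N2
    (eta_N2-N2O), both per mil, product-minus-substrate sign convention
    (normal fractionation negative).
    """

    eta_production: float
    eta_reduction: float
    pools: tuple[NitrogenPool, ...] = ()

    def __post_init__(self) -> None:
        if not np.isfinite(self.eta_production) or not np.isfinite(self.eta_reduction):
            raise ValueError("NIEs must be finite")

    def pool(self, name: str) -> NitrogenPool:
        for p in self.pools:
            if p.name == name:
                return p
        raise KeyError(name)


@dataclass(frozen=True)
class PoolState:
    """State of one pool at one time step."""

    time: float
    f_substrate: float
    delta_no3_residual: float
    delta_n2o_produced: float
    delta_n2o_emitted: float


@dataclass(frozen=True)
class PoolTrajectory:
    """Vectorised sequence of :class:`PoolState` for one pool."""

    pool: NitrogenPool
    times: np.ndarray
    f_substrate: np.ndarray
    delta_no3_residual: np.ndarray
    delta_n2o_produced: np.ndarray
    delta_n2o_emitted: np.ndarray

    def state(self, i: int) -> PoolState:
        return PoolState(self.times[i], self.f_substrate[i],
                         self.delta_no3_residual[i],
                         self.delta_n2o_produced[i],
                         self.delta_n2o_emitted[i])

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class ModelTrajectory:
    """Joint trajectory of the (one- or two-) pool simulation."""

    times: np.ndarray
    pool1: PoolTrajectory
    pool2: PoolTrajectory | None
    mixing_fraction: np.ndarray  # pool-1 share x1(t) of emitted N2O, in [0,1]
    delta_bulk_mixed: np.ndarray  # per mil, emitted delta15N-bulk


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting net isotope effects to an observed delta series."""

    params: RayleighParameters
    r_squared: float
    residuals: np.ndarray
    n_observations: int
    converged: bool
    n_starts: int
    best_start: tuple[float, ...]
    cost: float
    free_names: tuple[str, ...]
    seed: int | None = None


# ---------------------------------------------------------------------------
# scalar operations

def rayleigh_delta(delta_s0, f, eta):
    """Residual-substrate delta after consuming a fraction 1-f.

    Closed-system Rayleigh: ``(delta_S0 + 1000) * f**(eta/1000) - 1000``.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or np.any(f > 1):
        raise ValueError("f must lie in (0, 1]")
    d0 = np.asarray(delta_s0, dtype=float)
    if np.any(d0 <= -1000.0):
        raise ValueError("delta_s0 must exceed -1000 per mil")
    out = (d0 + 1000.0) * f ** (np.asarray(eta, dtype=float) / 1000.0) - 1000.0
    return float(out) if out.ndim == 0 else out


def fraction_substrate_remaining(n_initial_kg_ha: float, cumulative_loss_kg_ha,
                                 pool_name: str = "pool",
                                 times=None):
    """f = (N_initial - cumulative N2O+N2 loss) / N_initial.

    Raises :class:`SubstrateExhaustedError` (with the first offending time
    when ``times`` is given) if the loss reaches the initial nitrate.
    """
    if n_initial_kg_ha <= 0:
        raise ValueError("initial nitrate mass must be positive")
    loss = np.asarray(cumulative_loss_kg_ha, dtype=float)
    if np.any(loss < 0):
        raise ValueError("cumulative loss must be non-negative")
    exhausted = loss >= n_initial_kg_ha
    if np.any(exhausted):
        t_ex = None
        if times is not None:
            t_ex = float(np.asarray(times, dtype=float)[np.argmax(exhausted)])
        raise SubstrateExhaustedError(pool_name, t_ex)
    f = (n_initial_kg_ha - loss) / n_initial_kg_ha
    return float(f) if f.ndim == 0 else f


def delta_n2o_produced(delta_no3_residual, eta_production):
    """Instantaneous-product approximation: delta_residual + eta_production."""
    out = np.asarray(delta_no3_residual, dtype=float) + np.asarray(eta_production, dtype=float)
    return float(out) if out.ndim == 0 else out


def delta_n2o_emitted(delta_produced, r_n2o, eta_reduction, form: str = "closed"):
    """delta15N of N2O surviving partial reduction to N2.

    ``r_n2o`` (the product ratio) is the unreduced N2O fraction: the
    default closed-system form applies the Rayleigh curve with f = r_n2o;
    the open-system (steady-state) variant uses
    ``delta_produced - eta_reduction * (1 - r)``.  r = 0 is an error: all
    N2O was consumed, no emitted signature exists.
    """
    r = np.asarray(r_n2o, dtype=float)
    if np.any(r <= 0) or np.any(r > 1):
        raise ValueError("product ratio must lie in (0, 1]")
    if form == "closed":
        out = rayleigh_delta(delta_produced, r, eta_reduction)
    elif form == "open":
        out = (np.asarray(delta_produced, dtype=float)
               - np.asarray(eta_reduction, dtype=float) * (1.0 - r))
    else:
        raise ValueError("form must be 'closed' or 'open'")
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# simulation

def simulate_pool(pool: NitrogenPool,
                  cumulative_loss_kg_ha: np.ndarray,
                  ratio: ProductRatioSeries,
                  params: RayleighParameters,
                  reduction_form: str = "closed") -> PoolTrajectory:
    """Advance one pool through its loss series.

    Per time step: f from the cumulative N2O+N2 loss apportioned to this
    pool, residual-nitrate delta by Rayleigh with ``eta_production``,
    instantaneous-product delta, then the reduction shift at the product
    ratio.  Where the ratio is undefined (no flux) the emitted delta is
    carried as the produced delta — nothing is emitted there anyway.
    """
    times = ratio.times
    loss = np.asarray(cumulative_loss_kg_ha, dtype=float)
    if loss.shape != times.shape:
        raise ValueError("loss series must match the ratio time grid")
    if np.any(np.diff(loss) < -1e-12):
        raise ValueError("cumulative loss must be non-decreasing")
    f = fraction_substrate_remaining(pool.n_no3_initial_kg_ha, loss,
                                     pool_name=pool.name, times=times)
    d_res = rayleigh_delta(pool.delta_no3_initial, f, params.eta_production)
    d_prod = delta_n2o_produced(d_res, params.eta_production)
    d_emit = np.array(d_prod, dtype=float, copy=True)
    ok = ratio.defined & (ratio.r_n2o > 0)
    if np.any(ok):
        d_emit[ok] = delta_n2o_emitted(d_prod[ok], ratio.r_n2o[ok],
                                       params.eta_reduction, form=reduction_form)
    return PoolTrajectory(pool=pool, times=times, f_substrate=f,
                          delta_no3_residual=d_res,
                          delta_n2o_produced=d_prod,
                          delta_n2o_emitted=d_emit)


def _loss_split(n2o: GasFluxSeries, n2: GasFluxSeries,
                mixing: CubicMixingFunction | None):
    """Common grid, product ratio, x1(t) and per-pool cumulative losses.

    Increments of total N loss between grid points are apportioned to
    pool 1 by the mixing fraction at the interval midpoint.
    """
    ratio = product_ratio(n2o, n2)
    t = ratio.times
    f_n2o = np.interp(t, n2o.times, n2o.fluxes)
    f_n2 = np.interp(t, n2.times, n2.fluxes)
    total_flux = np.clip(f_n2o + f_n2, 0.0, None)
    cum_total = np.concatenate(([0.0], cumulative_trapezoid(total_flux, t)))
    if mixing is None:
        x1 = np.ones_like(t)
    else:
        x1 = np.asarray(evaluate_mixing(mixing, t)) / 100.0
    inc = np.diff(cum_total)
    t_mid = 0.5 * (t[:-1] + t[1:])
    if mixing is None:
        x1_mid = np.ones_like(t_mid)
    else:
        x1_mid = np.asarray(evaluate_mixing(mixing, t_mid)) / 100.0
    cum1 = np.concatenate(([0.0], np.cumsum(inc * x1_mid)))
    cum2 = cum_total - cum1
    return ratio, x1, cum1, cum2


def simulate_two_pool(params: RayleighParameters,
                      n2o: GasFluxSeries,
                      n2: GasFluxSeries,
                      mixing: CubicMixingFunction,
                      reduction_form: str = "closed") -> ModelTrajectory:
    """Two-pool forward simulation of emitted delta15N-bulk.

    x1(t) = mixing(t)/100 splits each step's N2O+N2 loss between the
    fertiliser and soil pools; each pool follows its own Rayleigh curve and
    the emitted bulk signal is the convex mixture
    ``x1 * delta1_emitted + (1 - x1) * delta2_emitted``.
    """
    pool1 = params.pool("pool1_fertiliser")
    pool2 = params.pool("pool2_soil")
    ratio, x1, cum1, cum2 = _loss_split(n2o, n2, mixing)
    traj1 = simulate_pool(pool1, cum1, ratio, params, reduction_form)
    traj2 = simulate_pool(pool2, cum2, ratio, params, reduction_form)
    mixed = x1 * traj1.delta_n2o_emitted + (1.0 - x1) * traj2.delta_n2o_emitted
    return ModelTrajectory(times=ratio.times, pool1=traj1, pool2=traj2,
                           mixing_fraction=x1, delta_bulk_mixed=mixed)


def simulate_one_pool(params: RayleighParameters,
                      n2o: GasFluxSeries,
                      n2: GasFluxSeries,
                      reduction_form: str = "closed") -> ModelTrajectory:
    """One-pool simulation: all emission from the fertiliser pool (x1 = 1)."""
    pool1 = params.pool("pool1_fertiliser")
    ratio, x1, cum1, _ = _loss_split(n2o, n2, mixing=None)
    traj1 = simulate_pool(pool1, cum1, ratio, params, reduction_form)
    mixed = x1 * traj1.delta_n2o_emitted
    return ModelTrajectory(times=ratio.times, pool1=traj1, pool2=None,
                           mixing_fraction=x1, delta_bulk_mixed=mixed)


# ---------------------------------------------------------------------------
# fitting

_FREE_PARAMS = {
    "eta_production": (-120.0, 10.0),
    "eta_reduction": (-120.0, 10.0),
    "delta_no3_initial_pool1": (-60.0, 60.0),
}


class _TwoPoolKernel:
    """Precomputed loss split so repeated NIE evaluations are cheap.

    f(t), the product ratio and x1(t) do not depend on the NIEs, so the
    mixed delta is a closed form in (eta_production, eta_reduction,
    delta_S0 of pool 1) on the fixed grid.
    """

    def __init__(self, params: RayleighParameters, n2o: GasFluxSeries,
                 n2: GasFluxSeries, mixing: CubicMixingFunction | None,
                 reduction_form: str = "closed"):
        self.pool1 = params.pool("pool1_fertiliser")
        self.pool2 = params.pool("pool2_soil") if mixing is not None else None
        self.reduction_form = reduction_form
        ratio, x1, cum1, cum2 = _loss_split(n2o, n2, mixing)
        self.times = ratio.times
        self.x1 = x1
        self.f1 = fraction_substrate_remaining(self.pool1.n_no3_initial_kg_ha,
                                               cum1, self.pool1.name, self.times)
        self.f2 = None
        if self.pool2 is not None:
            self.f2 = fraction_substrate_remaining(self.pool2.n_no3_initial_kg_ha,
                                                   cum2, self.pool2.name, self.times)
        self.r = np.where(ratio.defined & (ratio.r_n2o > 0), ratio.r_n2o, 1.0)

    def _emitted(self, d0, f, eta_p, eta_r):
        d_res = (d0 + 1000.0) * f ** (eta_p / 1000.0) - 1000.0
        d_prod = d_res + eta_p
        if self.reduction_form == "closed":
            return (d_prod + 1000.0) * self.r ** (eta_r / 1000.0) - 1000.0
        return d_prod - eta_r * (1.0 - self.r)

    def delta_mixed(self, eta_p, eta_r, d0_pool1=None):
        d0_1 = self.pool1.delta_no3_initial if d0_pool1 is None else d0_pool1
        d1 = self._emitted(d0_1, self.f1, eta_p, eta_r)
        if self.pool2 is None:
            return self.x1 * d1
        d2 = self._emitted(self.pool2.delta_no3_initial, self.f2, eta_p, eta_r)
        return self.x1 * d1 + (1.0 - self.x1) * d2


def fit_nie(observed_times,
            observed_delta,
            n2o: GasFluxSeries,
            n2: GasFluxSeries,
            mixing: CubicMixingFunction | None,
            pools: tuple[NitrogenPool, NitrogenPool] | tuple[NitrogenPool],
            free: tuple[str, ...] = ("eta_production", "eta_reduction"),
            start_grid_step: float = 10.0,
            reduction_form: str = "closed",
            seed: int | None = None) -> FitResult:
    """Fit net isotope effects to a measured delta15N-bulk series.

    Bounded nonlinear least squares with a deterministic multi-start grid
    (starts at every ``start_grid_step`` per mil across [-80, 0] for each
    free NIE).  ``mixing=None`` fits the one-pool model.  Raises if the
    optimiser fails to converge from every start.
    """
    obs_t = np.asarray(observed_times, dtype=float)
    obs_d = np.asarray(observed_delta, dtype=float)
    if obs_t.shape != obs_d.shape or obs_t.ndim != 1:
        raise ValueError("observed times/deltas must be 1-D and equal length")
    for name in free:
        if name not in _FREE_PARAMS:
            raise ValueError(f"unknown free parameter {name!r}")
    if obs_t.size < len(free):
        raise ValueError("need at least as many observations as free parameters")

    params0 = RayleighParameters(eta_production=0.0, eta_reduction=0.0, pools=tuple(pools))
    kernel = _TwoPoolKernel(params0, n2o, n2, mixing, reduction_form)
    if (obs_t.min() < kernel.times[0] - 1e-9) or (obs_t.max() > kernel.times[-1] + 1e-9):
        raise ValueError("observations outside the simulated time range")

    def unpack(theta):
        vals = {"eta_production": -30.0, "eta_reduction": -6.0,
                "delta_no3_initial_pool1": None}
        for name, v in zip(free, theta):
            vals[name] = v
        return vals

    def residual(theta):
        v = unpack(theta)
        model = kernel.delta_mixed(v["eta_production"], v["eta_reduction"],
                                   v["delta_no3_initial_pool1"])
        return np.interp(obs_t, kernel.times, model) - obs_d

    lo = np.array([_FREE_PARAMS[n][0] for n in free])
    hi = np.array([_FREE_PARAMS[n][1] for n in free])
    eta_starts = np.arange(-80.0, 0.0 + 1e-9, start_grid_step)
    grids = [eta_starts if n.startswith("eta") else np.array([0.0]) for n in free]
    starts = np.stack(np.meshgrid(*grids, indexing="ij"), axis=-1).reshape(-1, len(free))

    best = None
    best_start = None
    n_converged = 0
    for theta0 in starts:
        sol = least_squares(residual, theta0, bounds=(lo, hi), method="trf")
        if sol.success:
            n_converged += 1
            if best is None or sol.cost < best.cost - 1e-15:
                best, best_start = sol, theta0
    if best is None:
        raise RuntimeError("NIE fit failed to converge from every start")

    v = unpack(best.x)
    pool1 = params0.pool("pool1_fertiliser")
    if v["delta_no3_initial_pool1"] is not None:
        pool1 = replace(pool1, delta_no3_initial=float(v["delta_no3_initial_pool1"]))
    new_pools = tuple(pool1 if p.name == "pool1_fertiliser" else p for p in params0.pools)
    fitted = RayleighParameters(eta_production=float(v["eta_production"]),
                                eta_reduction=float(v["eta_reduction"]),
                                pools=new_pools)
    resid = residual(best.x)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((obs_d - obs_d.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res < 1e-20 else 0.0)
    return FitResult(params=fitted, r_squared=min(r2, 1.0), residuals=resid,
                     n_observations=obs_t.size, converged=True,
                     n_starts=len(starts), best_start=tuple(best_start),
                     cost=float(best.cost), free_names=tuple(free), seed=seed)
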