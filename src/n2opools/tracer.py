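"""15N-tracer partitioning of emitted N2O between nitrate pools.

In the labelled vessels the fertiliser nitrate carries 5 atom-% 15N against
a natural-abundance soil background, so the atom fraction of emitted
N2O-N is a two-end-member mixture.  The fraction derived from the
fertiliser pool, expressed in percent against elapsed time, is summarised
by an ordinary-least-squares cubic — the pool-mixing function that drives
the two-pool Rayleigh model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .vessels import NATURAL_ABUNDANCE_AT_PERCENT, R15_AIR_N2

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# delta <-> atom-fraction conversions (15N, air-N2 scale)

def delta_to_atom_fraction(delta_permil, r_std: float = R15_AIR_N2):
    """15N atom fraction x = R/(1+R) with R = r_std (delta/1000 + 1)."""
    r = r_std * (np.asarray(delta_permil, dtype=float) / 1000.0 + 1.0)
    return r / (1.0 + r)


def atom_fraction_to_delta(atom_fraction, r_std: float = R15_AIR_N2):
    """Inverse of :func:`delta_to_atom_fraction`."""
    x = np.asarray(atom_fraction, dtype=float)
    r = x / (1.0 - x)
    return (r / r_std - 1.0) * 1000.0


def delta_to_at_percent(delta_permil, r_std: float = R15_AIR_N2):
    return delta_to_atom_fraction(delta_permil, r_std) * 100.0


def at_percent_to_delta(at_percent, r_std: float = R15_AIR_N2):
    return atom_fraction_to_delta(np.asarray(at_percent, dtype=float) / 100.0, r_std)


# ---------------------------------------------------------------------------
# series containers

@dataclass(frozen=True)
class AtomFractionSeries:
    """Measured atom-% 15N of emitted N2O-N in a labelled vessel."""

    times: np.ndarray
    at_percent: np.ndarray
    a_fertiliser: float = 5.0
    a_background: float = NATURAL_ABUNDANCE_AT_PERCENT
    vessel_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "at_percent", np.asarray(self.at_percent, dtype=float))
        if self.times.shape != self.at_percent.shape:
            raise ValueError("times and at_percent must have equal length")
        if self.a_background >= self.a_fertiliser:
            raise ValueError("background at% must be below fertiliser at%")


@dataclass(frozen=True)
class SourceContributionSeries:
    """Percent of emitted N2O-N derived from the fertiliser pool per time."""

    times: np.ndarray
    percent_fertiliser: np.ndarray
    treatment: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        pct = np.clip(np.asarray(self.percent_fertiliser, dtype=float), 0.0, 100.0)
        object.__setattr__(self, "percent_fertiliser", pct)
        if self.times.shape != self.percent_fertiliser.shape:
            raise ValueError("times and percent_fertiliser must have equal length")


@dataclass(frozen=True)
class CubicMixingFunction:
    """f(x) = a3 x^3 + a2 x^2 + a1 x + a0: % of emitted N2O from pool 1.

    ``x`` is time after amendment in days; evaluation is clamped to
    [0, 100] %.  ``r_squared`` records the goodness of the calibration fit.
    """

    a3: float
    a2: float
    a1: float
    a0: float
    r_squared: float | None = None
    treatment: str | None = None

    def __post_init__(self) -> None:
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")

    @property
    def coefficients(self) -> tuple[float, float, float, float]:
        """(a3, a2, a1, a0), highest order first."""
        return (self.a3, self.a2, self.a1, self.a0)

    def __call__(self, t):
        return evaluate_mixing(self, t)


# ---------------------------------------------------------------------------
# operations

def fraction_from_fertiliser(sample_at_percent,
                             a_fertiliser: float = 5.0,
                             a_background: float = NATURAL_ABUNDANCE_AT_PERCENT,
                             tolerance_at_percent: float = 0.05):
    """Two-end-member mixing fraction of the fertiliser pool, in [0, 1].

    ``(sample - background) / (fertiliser - background)``, clamped to
    [0, 1].  Samples outside the end-member interval by more than
    ``tolerance_at_percent`` are logged — measurement noise near the
    end-members is expected, gross excursions are not.
    """
    if a_fertiliser <= a_background:
        raise ValueError("fertiliser at% must exceed background at%")
    sample = np.asarray(sample_at_percent, dtype=float)
    if not np.all(np.isfinite(sample)):
        raise ValueError("sample at% must be finite")
    out_of_range = ((sample < a_background - tolerance_at_percent)
                    | (sample > a_fertiliser + tolerance_at_percent))
    if np.any(out_of_range):
        log.warning("%d sample(s) outside end-member range [%g, %g] at%%; clamped",
                    int(np.sum(out_of_range)), a_background, a_fertiliser)
    frac = (sample - a_background) / (a_fertiliser - a_background)
    frac = np.clip(frac, 0.0, 1.0)
    return float(frac) if np.isscalar(sample_at_percent) else frac


def contribution_series(series: AtomFractionSeries,
                        treatment: str | None = None) -> SourceContributionSeries:
    """Convert a labelled-vessel atom-% series to percent-from-fertiliser."""
    frac = fraction_from_fertiliser(series.at_percent, series.a_fertiliser,
                                    series.a_background)
    return SourceContributionSeries(times=series.times,
                                    percent_fertiliser=100.0 * np.asarray(frac),
                                    treatment=treatment)


def fit_cubic_mixing(series: SourceContributionSeries) -> CubicMixingFunction:
    """Ordinary-least-squares cubic of percent-from-fertiliser vs time.

    Requires >= 5 distinct time points so the fit is overdetermined.
    R^2 = 1 - SS_res/SS_tot; for a zero-variance target R^2 is 1 when the
    residuals vanish and 0 otherwise (documented convention).
    """
    t = series.times
    y = series.percent_fertiliser
    if np.unique(t).size < 5:
        raise ValueError("need at least 5 distinct time points for a cubic fit")
    # polynomial.fit uses a scaled domain internally -> well-conditioned
    poly = np.polynomial.Polynomial.fit(t, y, deg=3).convert()
    coef = np.zeros(4)
    coef[: poly.coef.size] = poly.coef  # ascending order a0..a3
    resid = y - poly(t)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if np.allclose(resid, 0.0) else 0.0
    return CubicMixingFunction(a3=float(coef[3]), a2=float(coef[2]),
                               a1=float(coef[1]), a0=float(coef[0]),
                               r_squared=max(0.0, min(1.0, r2)),
                               treatment=series.treatment)


def evaluate_mixing(fn: CubicMixingFunction, t):
    """Evaluate the mixing cubic at time(s) ``t`` (days), clamped to [0, 100] %."""
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("time must be non-negative")
    val = ((fn.a3 * tt + fn.a2) * tt + fn.a1) * tt + fn.a0
    val = np.clip(val, 0.0, 100.0)
    return float(val) if np.isscalar(t) else val
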