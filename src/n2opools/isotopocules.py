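"""N2O isotopocule descriptors and the SP vs delta18O source map.

The linear N2O molecule carries 15N at the central (alpha) or peripheral
(beta) position.  Site preference SP = 2*(delta15N-alpha - delta15N-bulk)
is a process indicator independent of the precursor's signature; combined
with delta18O it places samples relative to literature endmember regions
(bacterial/fungal denitrification, nitrification) and to reduction lines
along which residual N2O moves as it is reduced to N2.

Endmember coordinates and reduction NIEs originate in the literature and
are user-supplied configuration here, not package defaults.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from shapely.geometry import Point, Polygon

from .rayleigh import rayleigh_delta


@dataclass(frozen=True)
class IsotopocouleRecord:
    """One sampling time's N2O isotope descriptors (all per mil).

    Invariants: ``sp == 2*(delta_alpha - delta_bulk)`` and
    ``delta_bulk == (delta_alpha + delta_beta)/2``.
    """

    time: float
    delta_bulk: float
    delta_alpha: float
    delta_beta: float
    delta_o18: float
    sp: float

    @classmethod
    def from_alpha(cls, time: float, delta_bulk: float, delta_alpha: float,
                   delta_o18: float) -> "IsotopocouleRecord":
        return cls(time=time, delta_bulk=delta_bulk, delta_alpha=delta_alpha,
                   delta_beta=delta_beta(delta_alpha, delta_bulk),
                   delta_o18=delta_o18,
                   sp=site_preference(delta_alpha, delta_bulk))

    @classmethod
    def from_sp(cls, time: float, delta_bulk: float, sp: float,
                delta_o18: float) -> "IsotopocouleRecord":
        alpha = delta_bulk + sp / 2.0
        return cls.from_alpha(time, delta_bulk, alpha, delta_o18)


def site_preference(delta_alpha, delta_bulk):
    """SP = 2 * (delta15N-alpha - delta15N-bulk)."""
    out = 2.0 * (np.asarray(delta_alpha, dtype=float)
                 - np.asarray(delta_bulk, dtype=float))
    return float(out) if out.ndim == 0 else out


def delta_beta(delta_alpha, delta_bulk):
    """delta15N-beta = 2*delta_bulk - delta_alpha (bulk is the alpha/beta mean)."""
    out = (2.0 * np.asarray(delta_bulk, dtype=float)
           - np.asarray(delta_alpha, dtype=float))
    return float(out) if out.ndim == 0 else out


def dual_isotope_slope(delta_o18, delta_bulk, transpose: bool = False):
    """OLS slope of delta15N-bulk on delta18O (or transposed).

    Returns ``(slope, intercept, stderr)``.  Requires >= 3 pairs and
    variance in the regressor.
    """
    x = np.asarray(delta_o18, dtype=float)
    y = np.asarray(delta_bulk, dtype=float)
    if transpose:
        x, y = y, x
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the regressor")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.stderr)


# ---------------------------------------------------------------------------
# SP-delta18O map

@dataclass(frozen=True)
class EndmemberMap:
    """Polygonal endmember regions plus reduction-line geometry.

    ``regions`` maps process labels to polygons in (delta18O, SP) space.
    Reduction lines are anchored at the bacterial-denitrification endmember
    ``anchor`` = (delta18O, SP); their slopes span
    [``slope_min``, ``slope_max``] = the reported range of the ratio of the
    SP and delta18O reduction NIEs.  ``eta_sp_reduction`` (per mil, on SP)
    parameterises the Rayleigh inversion of reduction progress.
    """

    regions: dict[str, Polygon]
    anchor: tuple[float, float]
    slope_min: float
    slope_max: float
    eta_sp_reduction: float = -6.0

    def __post_init__(self) -> None:
        if self.slope_min > self.slope_max:
            raise ValueError("slope_min must be <= slope_max")
        for name, poly in self.regions.items():
            if poly.area <= 0:
                raise ValueError(f"region {name!r} is degenerate")
        if self.eta_sp_reduction >= 0:
            raise ValueError("eta_sp_reduction must be negative "
                             "(residual N2O enriches during reduction)")

    @classmethod
    def from_dict(cls, cfg: dict) -> "EndmemberMap":
        regions = {name: Polygon(coords) for name, coords in cfg["regions"].items()}
        return cls(regions=regions, anchor=tuple(cfg["anchor"]),
                   slope_min=float(cfg["slope_min"]),
                   slope_max=float(cfg["slope_max"]),
                   eta_sp_reduction=float(cfg.get("eta_sp_reduction", -6.0)))

    @classmethod
    def from_json(cls, path: str | Path) -> "EndmemberMap":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class MapClassification:
    """Label plus, where applicable, a reduction-progress estimate.

    ``reduction_progress`` = 1 - f, the fraction of initially produced N2O
    reduced to N2 along the path from the anchor; ``None`` off-path.
    """

    label: str
    reduction_progress: float | None = None


def reduction_progress_from_sp(sp: float, map_: EndmemberMap) -> float:
    """Invert the closed-system Rayleigh SP shift: progress = 1 - f."""
    sp0 = map_.anchor[1]
    f = ((sp + 1000.0) / (sp0 + 1000.0)) ** (1000.0 / map_.eta_sp_reduction)
    return 1.0 - float(np.clip(f, 0.0, 1.0))


def displace_along_reduction(map_: EndmemberMap, f: float,
                             slope: float | None = None) -> tuple[float, float]:
    """Forward model: (delta18O, SP) of anchor N2O after reduction to fraction f.

    SP moves by Rayleigh with ``eta_sp_reduction``; delta18O moves with the
    NIE implied by the chosen slope (midpoint of the range by default).
    """
    if slope is None:
        slope = 0.5 * (map_.slope_min + map_.slope_max)
    o18_0, sp0 = map_.anchor
    sp = rayleigh_delta(sp0, f, map_.eta_sp_reduction)
    eta_o18 = map_.eta_sp_reduction / slope
    o18 = rayleigh_delta(o18_0, f, eta_o18)
    return float(o18), float(sp)


def classify_sp_o18(record: IsotopocouleRecord,
                    map_: EndmemberMap) -> MapClassification:
    """Place a sample on the SP vs delta18O map.

    Points inside a configured region take that region's label; otherwise
    points lying between the minimum and maximum reduction lines (anchored
    at the bacterial endmember, towards increasing delta18O) are labelled
    ``"on-reduction-path"``; anything else is ``"unclassified"``.  Whenever
    the point sits on the reduction path (including inside the bacterial
    region), reduction progress is estimated from the SP displacement via
    the closed-system Rayleigh relation.
    """
    if map_ is None:
        raise ValueError("an EndmemberMap must be supplied")
    pt = Point(record.delta_o18, record.sp)
    d_o18 = record.delta_o18 - map_.anchor[0]
    d_sp = record.sp - map_.anchor[1]
    on_path = False
    if abs(d_o18) < 1e-12 and abs(d_sp) < 1e-12:
        on_path = True
    elif d_o18 > 0:
        slope = d_sp / d_o18
        on_path = map_.slope_min - 1e-12 <= slope <= map_.slope_max + 1e-12
    progress = reduction_progress_from_sp(record.sp, map_) if on_path else None
    for label, poly in map_.regions.items():
        if poly.covers(pt):
            return MapClassification(label=label, reduction_progress=progress)
    if on_path:
        return MapClassification(label="on-reduction-path",
                                 reduction_progress=progress)
    return MapClassification(label="unclassified")
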