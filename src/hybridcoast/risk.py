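"""Flood impacts and risk-curve integration.

Per-event impact in a cell combines depth-damage fractions per occupancy
type with that cell's maximum damages:

    I(w) = theta_r(w) M_r + theta_c(w) M_c + theta_i(w) M_i

with the damage fraction reaching 1 at 6 m inundation depth.  Expected
annual damage (EAD) is the integral of the impact over annual exceedance
probability, evaluated by the trapezoidal rule over the simulated return
periods; the curve is truncated at the exceedance probability of the local
protection standard, and the unsimulated tail beyond the largest return
period contributes a rectangle (optional).  Expected annual affected
population (EAAP) uses the identical integration routine with exposed
population in place of damage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

logger = logging.getLogger(__name__)

#: occupancy shares of built-up area: residential, commercial, industrial
OCCUPANCY_SHARES = {"r": 0.75, "c": 0.15, "i": 0.10}
#: building footprint density within the occupancy share
BUILDING_DENSITY = {"r": 0.20, "c": 0.30, "i": 0.30}
#: construction cost [currency/m2] at the reference GDP per capita
UNIT_COST = 1000.0
GDP_PC_REFERENCE = 10000.0
#: depth at which damage fractions saturate [m]
SATURATION_DEPTH = 6.0


@dataclass(frozen=True)
class DepthDamageCurve:
    """Monotone depth -> damage-fraction maps per occupancy type.

    Default: piecewise linear from (0, 0) to (6 m, 1) for all three types.
    """

    depths: np.ndarray = field(
        default_factory=lambda: np.array([0.0, SATURATION_DEPTH]))
    fractions: dict = field(default_factory=lambda: {
        "r": np.array([0.0, 1.0]), "c": np.array([0.0, 1.0]),
        "i": np.array([0.0, 1.0])})

    def __post_init__(self):
        d = np.asarray(self.depths, dtype=float)
        if d[0] != 0.0 or np.any(np.diff(d) <= 0):
            raise ParameterError("depths must start at 0, strictly increase")
        for occ, f in self.fractions.items():
            f = np.asarray(f, dtype=float)
            if f[0] != 0.0 or np.any(np.diff(f) < 0) or f[-1] > 1.0:
                raise ParameterError(
                    f"damage fractions for {occ!r} must be nondecreasing, "
                    "start at 0 and stay within [0, 1]")

    def theta(self, depth, occ: str):
        """Damage fraction at ``depth`` (>= 6 m saturates at the maximum)."""
        w = np.clip(np.asarray(depth, dtype=float), 0.0, None)
        return np.interp(w, self.depths, self.fractions[occ],
                         right=float(self.fractions[occ][-1]))


@dataclass(frozen=True)
class MaxDamages:
    """Maximum damages [currency] per cell and occupancy type."""

    Mr: np.ndarray
    Mc: np.ndarray
    Mi: np.ndarray

    def total(self):
        return self.Mr + self.Mc + self.Mi


def build_max_damages(world, unit_cost: float = UNIT_COST,
                      gdp_pc_reference: float = GDP_PC_REFERENCE) -> MaxDamages:
    """Maximum damages from built-up fraction, occupancy shares, building
    densities and a unit construction cost scaled linearly with the region's
    GDP per capita relative to a reference."""
    cell_m2 = world.config.cell_size_m ** 2
    scale = np.ones(world.shape)
    for r in world.regions:
        scale[r.row_slice[0]:r.row_slice[1], :] = \
            world.gdp_pc(r.id) / gdp_pc_reference
    base = world.builtup * cell_m2 * unit_cost * scale
    out = {}
    for occ in ("r", "c", "i"):
        out[occ] = base * OCCUPANCY_SHARES[occ] * BUILDING_DENSITY[occ]
    return MaxDamages(Mr=out["r"], Mc=out["c"], Mi=out["i"])


def cell_impact(depth, maxdam: MaxDamages,
                curve: DepthDamageCurve | None = None):
    """Event impact per cell at inundation depth ``depth`` [m]."""
    curve = curve or DepthDamageCurve()
    return (curve.theta(depth, "r") * maxdam.Mr
            + curve.theta(depth, "c") * maxdam.Mc
            + curve.theta(depth, "i") * maxdam.Mi)


@dataclass
class RiskCurve:
    """Impact versus annual probability, truncated at the protection level.

    ``p`` are annual probabilities 1/T in (0, 1]; impacts are nonincreasing
    in p (rarer events hit harder). ``p_prot`` = 1/T_protection.
    """

    p: np.ndarray
    impact: np.ndarray
    p_prot: float = 1.0

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        im = np.asarray(self.impact, dtype=float)
        if p.size == 0 or p.size != im.size:
            raise ParameterError("risk curve needs matched nonempty p/impact")
        if np.any(p <= 0) or np.any(p > 1):
            raise ParameterError("p must lie in (0, 1]")
        if not (0 < self.p_prot <= 1):
            raise ParameterError("p_prot must lie in (0, 1]")
        if np.any(np.diff(p) < 0):
            logger.warning("risk curve p not sorted; sorting internally")
            order = np.argsort(p)
            p, im = p[order], im[order]
        self.p = p
        self.impact = im

    @classmethod
    def from_return_periods(cls, return_periods, impacts,
                            protection_rp: float = None) -> "RiskCurve":
        rp = np.asarray(return_periods, dtype=float)
        p = 1.0 / rp
        order = np.argsort(p)
        p_prot = 1.0 if protection_rp is None else 1.0 / protection_rp
        return cls(p=p[order], impact=np.asarray(impacts, float)[order],
                   p_prot=min(p_prot, 1.0))


def expected_annual(curve: RiskCurve, include_tail: bool = True) -> float:
    """Trapezoidal integral of the truncated risk curve [currency/yr].

    Impacts at probabilities above ``p_prot`` are zeroed (the defended
    range); the impact exactly at ``p_prot`` is obtained by linear
    interpolation in p between bracketing points; the unsimulated tail
    beyond the largest simulated return period contributes the rectangle
    I(p_min) * p_min unless ``include_tail`` is false.
    """
    p, im = curve.p, curve.impact
    p_prot = curve.p_prot
    p_min = p[0]
    tail = float(im[0] * p_min) if include_tail else 0.0
    if p_prot <= p_min:
        return tail
    # interpolate impact at the truncation probability, keep points below it
    i_prot = float(np.interp(p_prot, p, im))
    keep = p < p_prot
    pp = np.concatenate([p[keep], [p_prot]])
    ii = np.concatenate([im[keep], [i_prot]])
    return float(np.trapezoid(ii, pp)) + tail


def exposed_population(pop: np.ndarray, depth_grid) -> float:
    """Population in cells with positive inundation depth."""
    if pop.shape != depth_grid.depth.shape:
        raise ParameterError("population and depth grids not co-registered")
    return float(pop[depth_grid.flooded].sum())


def eaap(pop: np.ndarray, depth_stack: dict, protection_rp: float,
         include_tail: bool = True) -> float:
    """Expected annual affected population: exposed population per return
    period integrated with the same routine as EAD."""
    rps = sorted(depth_stack)
    exposed = [exposed_population(pop, depth_stack[T]) for T in rps]
    curve = RiskCurve.from_return_periods(rps, exposed,
                                          protection_rp=protection_rp)
    return expected_annual(curve, include_tail=include_tail)


def restoration_benefit(risk_without: float, risk_with: float) -> float:
    """Avoided expected annual damage B = D_without - D_with.

    A negative value indicates inconsistent inputs (restoration can only
    raise protection); it is flagged, not clipped.
    """
    b = risk_without - risk_with
    if b < -1e-9:
        logger.warning("negative restoration benefit %.3g: with-restoration "
                       "risk exceeds without-restoration risk", b)
    return b
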