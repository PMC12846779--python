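"""Dike overtopping, crest design, and protection-level bookkeeping.

Overtopping of a smooth 1:3 dike without berms is estimated with the
mean-value empirical formulas for sloped structures: the breaking-wave branch

    q_break = sqrt(g Hm0^3) * (0.023 / sqrt(tan a)) * xi
              * exp(-(2.7 Rc / (xi Hm0))^1.3)

capped by the maximum branch

    q_max = sqrt(g Hm0^3) * 0.09 * exp(-(1.5 Rc / Hm0)^1.3)

with all roughness/obliqueness influence factors set to 1 and the breaker
parameter xi = tan a / sqrt(2 pi Hm0 / (g Tm^2)).  ``required_freeboard``
inverts the pair in closed form.  Protection standards follow an
income-and-urbanisation table spanning 2-y to 1,000-y return periods, and
``effective_protection`` re-evaluates a fixed crest against rising seas and
changing mangrove state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import ConfigurationError, ParameterError
from .foreshore import (AttenuationLookup, Transect, transect_nearshore_hs)

logger = logging.getLogger(__name__)

G = 9.81
#: fixed deep-water wave steepness used to derive the mean period from Hs
WAVE_STEEPNESS = 0.04
#: number of log-spaced return periods scanned by effective_protection
PROTECTION_GRID_N = 60
PROTECTION_RANGE = (2.0, 1000.0)

#: protection standard (years) by income group x (rural, urban);
#: urban means urbanisation >= 0.5
FLOPROS_TABLE = {
    "low": (2, 10),
    "lower-middle": (5, 25),
    "upper-middle": (10, 100),
    "high": (50, 1000),
}


@dataclass(frozen=True)
class DikeSpec:
    """Standard dike profile: 1:3 slope, no berms, all influence factors 1."""

    crest_elevation: float
    tan_alpha: float = 1.0 / 3.0
    q_allow: float = 0.001  # 1 l/s/m

    def __post_init__(self):
        if self.tan_alpha <= 0:
            raise ParameterError("tan_alpha must be > 0")
        if self.q_allow <= 0:
            raise ParameterError("q_allow must be > 0")


@dataclass(frozen=True)
class ProtectionStandard:
    """Return period (years) up to which defenses prevent flooding."""

    return_period: float

    def __post_init__(self):
        lo, hi = PROTECTION_RANGE
        if not (lo <= self.return_period <= hi):
            raise ParameterError(
                f"protection standard {self.return_period} outside [{lo}, {hi}]")


class ProtectionLevel(NamedTuple):
    return_period: float
    substandard: bool


def mean_period(hm0: float, steepness: float = WAVE_STEEPNESS) -> float:
    """Mean wave period from Hs via a fixed deep-water steepness
    s = Hm0 / L0 with L0 = g Tm^2 / (2 pi)."""
    if hm0 <= 0:
        return 0.0
    return math.sqrt(2.0 * math.pi * hm0 / (G * steepness))


def _xi(hm0: float, tm: float, tan_alpha: float) -> float:
    """Breaker (Iribarren) parameter on the deep-water steepness."""
    s0 = 2.0 * math.pi * hm0 / (G * tm * tm)
    return tan_alpha / math.sqrt(s0)


def overtopping_discharge(hm0: float, rc: float, tan_alpha: float = 1.0 / 3.0,
                          tm: float | None = None) -> float:
    """Mean overtopping discharge q [m3/s/m] for freeboard ``rc``.

    Returns 0 when there are no waves. Strictly decreasing in ``rc``.
    """
    if hm0 <= 0:
        return 0.0
    if rc < 0:
        raise ParameterError("freeboard rc must be >= 0")
    if tan_alpha <= 0:
        raise ParameterError("tan_alpha must be > 0")
    if tm is None:
        tm = mean_period(hm0)
    if tm <= 0:
        raise ParameterError("tm must be > 0")
    xi = _xi(hm0, tm, tan_alpha)
    qs = math.sqrt(G * hm0 ** 3)
    q_break = qs * (0.023 / math.sqrt(tan_alpha)) * xi \
        * math.exp(-((2.7 * rc / (xi * hm0)) ** 1.3))
    q_max = qs * 0.09 * math.exp(-((1.5 * rc / hm0) ** 1.3))
    return min(q_break, q_max)


def required_freeboard(hm0: float, tm: float | None = None,
                       tan_alpha: float = 1.0 / 3.0,
                       q_allow: float = 0.001) -> float:
    """Smallest freeboard with ``overtopping_discharge(rc) <= q_allow``.

    Both branches are inverted in closed form; since q is the minimum of the
    branches, the required freeboard is the smaller of the two candidates.
    """
    if q_allow <= 0:
        raise ParameterError("q_allow must be > 0")
    if hm0 <= 0:
        return 0.0
    if tm is None:
        tm = mean_period(hm0)
    xi = _xi(hm0, tm, tan_alpha)
    qs = math.sqrt(G * hm0 ** 3)
    a_break = qs * (0.023 / math.sqrt(tan_alpha)) * xi
    a_max = qs * 0.09
    candidates = []
    for a, coef, scale in ((a_break, 2.7, xi * hm0), (a_max, 1.5, hm0)):
        if a <= q_allow:
            candidates.append(0.0)
        else:
            candidates.append((scale / coef) * math.log(a / q_allow) ** (1.0 / 1.3))
    return max(min(candidates), 0.0)


def flopros_standard(income_group: str, urbanization: float,
                     table: dict | None = None) -> ProtectionStandard:
    """Protection standard from the income-group/urbanisation default table."""
    table = FLOPROS_TABLE if table is None else table
    if income_group not in table:
        raise ConfigurationError(f"unknown income_group {income_group!r}")
    if not (0.0 <= urbanization <= 1.0):
        raise ParameterError("urbanization must be within [0, 1]")
    rural, urban = table[income_group]
    rp = urban if urbanization >= 0.5 else rural
    return ProtectionStandard(float(rp))


def _nearshore_hs(transect: Transect, swl: float, hs_offshore: float,
                  state: str, lut: AttenuationLookup | None) -> float:
    return transect_nearshore_hs(transect, swl, hs_offshore,
                                 transect.veg_width(state), lut)


def design_crest(transect: Transect, standard: ProtectionStandard,
                 mangrove_state: str = "current",
                 lut: AttenuationLookup | None = None,
                 dike: DikeSpec | None = None) -> DikeSpec:
    """Crest elevation delivering the design standard under the given
    mangrove state (existing dikes are designed with *current* mangroves)."""
    T = standard.return_period
    swl = transect.hazard.wl(T)
    hs = _nearshore_hs(transect, swl, transect.hazard.hs(T), mangrove_state, lut)
    tan_alpha = dike.tan_alpha if dike else 1.0 / 3.0
    q_allow = dike.q_allow if dike else 0.001
    rc = required_freeboard(hs, tan_alpha=tan_alpha, q_allow=q_allow)
    return DikeSpec(crest_elevation=swl + rc, tan_alpha=tan_alpha,
                    q_allow=q_allow)


def effective_protection(transect: Transect, dike: DikeSpec,
                         mangrove_state: str = "current", year: int = 2020,
                         scenario=None, percentile: int = 50,
                         lut: AttenuationLookup | None = None,
                         n_grid: int = PROTECTION_GRID_N,
                         with_flag: bool = False):
    """Largest return period the fixed crest still withstands.

    Scans ``n_grid`` log-spaced return periods on [2, 1000] and returns the
    largest T with WL(T) + SLR + required freeboard <= crest. If even T = 2
    fails, returns 2 flagged substandard. Restoration only raises the result.
    """
    slr = 0.0
    if scenario is not None:
        slr = scenario.slr_offset(year, percentile)
    lo, hi = PROTECTION_RANGE
    grid = np.exp(np.linspace(math.log(lo), math.log(hi), n_grid))
    best = None
    for T in grid:
        swl = transect.hazard.wl(T) + slr
        hs = _nearshore_hs(transect, swl, transect.hazard.hs(T),
                           mangrove_state, lut)
        rc = required_freeboard(hs, tan_alpha=dike.tan_alpha,
                                q_allow=dike.q_allow)
        if swl + rc <= dike.crest_elevation + 1e-9:
            best = T
        else:
            break  # requirement is nondecreasing in T
    if best is None:
        logger.warning("transect %s substandard (fails even T=2) at year %s",
                       transect.id, year)
        result = ProtectionLevel(lo, True)
    else:
        result = ProtectionLevel(float(best), False)
    return result if with_flag else result.return_period
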