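"""Benefit-cost analysis of mangrove restoration.

Annual benefit and cost streams run from the restoration year (2020) to
2100.  Benefits are avoided expected annual damages, scaled by the survival
rate and by a regrowth factor 1 - exp(-k (t - t0)) that saturates (99%) ten
years after planting.  Costs book the implementation cost (plus opportunity
costs of 1.4x implementation, as a year-0 lump sum) and annual maintenance
of 1% of implementation cost, scaled with GDP growth and survival.  Streams
are discounted to the benefit-cost ratio (BCR) and net present value (NPV);
the identity sign(NPV) = sign(BCR - 1) holds exactly.  Subnational regions
with less than 5 ha of restorable mangrove area are excluded.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AssignmentError, ParameterError

logger = logging.getLogger(__name__)

RESTORATION_YEAR = 2020
HORIZON = 2100
YEARS = np.arange(RESTORATION_YEAR, HORIZON + 1)

#: regrowth constant [1/yr]: 99% of full protective capacity at 10 years
DEFAULT_K = math.log(100.0) / 10.0
OPPORTUNITY_MULTIPLIER = 1.4
MAINTENANCE_RATE = 0.01
SURVIVAL_RATES = (0.50, 0.75, 0.90)
DISCOUNT_RATES = (0.03, 0.05, 0.08, 0.10)
MIN_AREA_HA = 5.0


@dataclass(frozen=True)
class CostModel:
    implementation_cost_per_ha: float = 8143.0
    opportunity_multiplier: float = OPPORTUNITY_MULTIPLIER
    maintenance_rate: float = MAINTENANCE_RATE
    survival_rate: float = 0.75
    discount_rate: float = 0.05
    k: float = DEFAULT_K
    t0: int = RESTORATION_YEAR
    horizon: int = HORIZON

    def __post_init__(self):
        if not (0.0 < self.survival_rate < 1.0):
            raise ParameterError("survival_rate must be in (0, 1)")
        if not (0.0 < self.maintenance_rate < 1.0):
            raise ParameterError("maintenance_rate must be in (0, 1)")
        if self.opportunity_multiplier <= 0 or self.k <= 0:
            raise ParameterError("opportunity_multiplier and k must be > 0")


@dataclass
class CashflowSeries:
    """Aligned annual benefits and costs, 2020..2100."""

    years: np.ndarray
    benefits: np.ndarray
    costs: np.ndarray

    def __post_init__(self):
        if not (len(self.years) == len(self.benefits) == len(self.costs)):
            raise ParameterError("cashflow series lengths differ")
        if np.any(self.benefits < 0) or np.any(self.costs < 0):
            raise ParameterError("cashflows must be nonnegative")


@dataclass
class BcaResult:
    region_id: object
    disc_benefits: float
    disc_costs: float
    bcr: float
    npv: float
    discount_rate: float
    survival_rate: float
    include_opportunity: bool
    area_ha: float = 0.0
    bcr_defined: bool = True


def growth_factor(t: float, t0: float = RESTORATION_YEAR,
                  k: float = DEFAULT_K):
    """Regrowth fraction 1 - exp(-k (t - t0)); 0 before planting."""
    if k <= 0:
        raise ParameterError("k must be > 0")
    dt = np.asarray(t, dtype=float) - t0
    out = np.where(dt >= 0, 1.0 - np.exp(-k * np.maximum(dt, 0.0)), 0.0)
    return float(out) if np.isscalar(t) else out


def cost_stream(area_ha: float, cost_model: CostModel,
                gdp_growth_factor=None,
                include_opportunity: bool = True) -> np.ndarray:
    """Annual costs 2020..2100 for restoring ``area_ha`` hectares.

    Year 0 books implementation (and, optionally, opportunity) costs as a
    lump sum; subsequent years book maintenance at 1% of implementation
    cost, scaled by the country's GDP growth and by the survival rate (only
    the surviving stand is maintained). Survival does not reduce the
    implementation outlay.
    """
    if area_ha < 0:
        raise ParameterError("area_ha must be >= 0")
    cm = cost_model
    ic = cm.implementation_cost_per_ha * area_ha
    years = np.arange(cm.t0, cm.horizon + 1)
    costs = np.zeros(years.size)
    costs[0] = ic * (1.0 + cm.opportunity_multiplier if include_opportunity
                     else 1.0)
    gdp = (np.array([gdp_growth_factor(y) for y in years[1:]])
           if gdp_growth_factor is not None else np.ones(years.size - 1))
    costs[1:] = cm.maintenance_rate * ic * gdp * cm.survival_rate
    return costs


def benefit_stream(annual_potential_benefit, cost_model: CostModel) -> np.ndarray:
    """Annual benefits B_t = s * regrowth(t) * potential(t), 2020..2100."""
    cm = cost_model
    years = np.arange(cm.t0, cm.horizon + 1)
    pot = np.array([float(annual_potential_benefit(y)) for y in years])
    return cm.survival_rate * growth_factor(years, cm.t0, cm.k) * pot


def discounted_bcr_npv(series: CashflowSeries, r: float,
                       region_id=None, **meta) -> BcaResult:
    """Discount a cashflow series to BCR and NPV (base year = first year)."""
    if r <= -1:
        raise ParameterError("discount rate must exceed -1")
    t = series.years - series.years[0]
    disc = (1.0 + r) ** (-t.astype(float))
    b = float(np.dot(series.benefits, disc))
    c = float(np.dot(series.costs, disc))
    npv = b - c
    if c > 0:
        bcr, defined = b / c, True
    else:
        bcr, defined = math.nan, False
        logger.warning("zero discounted costs for region %s: BCR undefined",
                       region_id)
    return BcaResult(region_id=region_id, disc_benefits=b, disc_costs=c,
                     bcr=bcr, npv=npv, discount_rate=r,
                     survival_rate=meta.pop("survival_rate", math.nan),
                     include_opportunity=meta.pop("include_opportunity", True),
                     area_ha=meta.pop("area_ha", 0.0), bcr_defined=defined)


@dataclass
class RegionEconomics:
    """Inputs the BCA needs for one subnational region."""

    region_id: object
    country_id: object
    area_ha: float
    #: callable year -> avoided EAD at full (saturated, surviving) capacity
    potential_benefit: object
    implementation_cost_per_ha: float
    gdp_growth_factor: object = None  # callable year -> factor


def region_bca(inputs: RegionEconomics, r: float = 0.05, s: float = 0.75,
               include_opportunity: bool = True,
               k: float = DEFAULT_K) -> BcaResult:
    cm = CostModel(implementation_cost_per_ha=inputs.implementation_cost_per_ha,
                   survival_rate=s, discount_rate=r, k=k)
    costs = cost_stream(inputs.area_ha, cm, inputs.gdp_growth_factor,
                        include_opportunity)
    benefits = benefit_stream(inputs.potential_benefit, cm)
    series = CashflowSeries(years=YEARS.copy(), benefits=benefits, costs=costs)
    return discounted_bcr_npv(series, r, region_id=inputs.region_id,
                              survival_rate=s,
                              include_opportunity=include_opportunity,
                              area_ha=inputs.area_ha)


def sensitivity_grid(regions: list, rates=DISCOUNT_RATES,
                     survivals=SURVIVAL_RATES,
                     opportunity=(True, False)) -> pd.DataFrame:
    """BCA per region over the full discount x survival x opportunity grid."""
    rows = []
    for r, s, opp in itertools.product(rates, survivals, opportunity):
        for reg in regions:
            res = region_bca(reg, r=r, s=s, include_opportunity=opp)
            rows.append({"region": res.region_id, "country": reg.country_id,
                         "area_ha": reg.area_ha,
                         "disc_benefits": res.disc_benefits,
                         "disc_costs": res.disc_costs, "bcr": res.bcr,
                         "npv": res.npv, "r": r, "s": s, "opportunity": opp})
    return pd.DataFrame(rows)


@dataclass
class AggregationResult:
    retained: list                # RegionEconomics passing the area rule
    excluded: list = field(default_factory=list)   # (region_id, area_ha)


def aggregate_regions(transect_areas_ha: dict, transect_benefits: dict,
                      transect_region: dict, region_meta: dict,
                      min_area_ha: float = MIN_AREA_HA) -> AggregationResult:
    """Sum per-transect restorable areas and potential-benefit series into
    regions, dropping regions with restorable area strictly below
    ``min_area_ha`` (logged in the exclusion list).

    ``transect_benefits`` maps transect id -> callable(year) -> currency/yr;
    ``region_meta`` maps region id -> (country_id, implementation cost/ha,
    gdp growth callable).
    """
    per_region_area, per_region_tids = {}, {}
    for tid, area in transect_areas_ha.items():
        if tid not in transect_region:
            raise AssignmentError(f"transect {tid} has no region assignment")
        rid = transect_region[tid]
        per_region_area[rid] = per_region_area.get(rid, 0.0) + area
        per_region_tids.setdefault(rid, []).append(tid)
    retained, excluded = [], []
    for rid, area in sorted(per_region_area.items()):
        if area < min_area_ha:
            excluded.append((rid, area))
            logger.info("region %s excluded: restorable area %.2f ha < %.1f",
                        rid, area, min_area_ha)
            continue
        tids = per_region_tids[rid]
        funcs = [transect_benefits[t] for t in tids]

        def summed(year, _funcs=tuple(funcs)):
            return sum(f(year) for f in _funcs)

        country, ic, gdp = region_meta[rid]
        retained.append(RegionEconomics(region_id=rid, country_id=country,
                                        area_ha=area,
                                        potential_benefit=summed,
                                        implementation_cost_per_ha=ic,
                                        gdp_growth_factor=gdp))
    return AggregationResult(retained=retained, excluded=excluded)
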