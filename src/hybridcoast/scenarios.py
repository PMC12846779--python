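"""Climate and socioeconomic scenario application.

Hazard, terrain and exposure are adjusted to any year in [2020, 2100]:
sea-level offsets shift the extreme water-level curves, subsidence lowers
the DEM, and country-level GDP/population growth scales maximum damages and
population. Risk is computed at three epochs (2020, 2050, 2080) and
interpolated to annual series; beyond 2080 the 2050-2080 slope is
extrapolated and floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ParameterError

EPOCHS = (2020, 2050, 2080)
YEAR_RANGE = (2020, 2100)


@dataclass(frozen=True)
class EpochSeries:
    """Values at the risk epochs with piecewise-linear annual interpolation."""

    epochs: tuple = EPOCHS
    values: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if len(self.epochs) != len(self.values):
            raise ParameterError("epochs and values lengths differ")
        if any(np.diff(self.epochs) <= 0):
            raise ParameterError("epochs must be strictly increasing")

    def interpolate(self, year: float) -> float:
        e = np.asarray(self.epochs, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if year <= e[-1]:
            return float(np.interp(year, e, v))
        # extrapolate with the last inter-epoch slope, floored at 0
        slope = (v[-1] - v[-2]) / (e[-1] - e[-2])
        return max(float(v[-1] + slope * (year - e[-1])), 0.0)


def epoch_interpolate(series: EpochSeries, year: float) -> float:
    """Annual value from epoch snapshots (see :class:`EpochSeries`)."""
    lo, hi = YEAR_RANGE
    if not (lo <= year <= hi):
        raise ParameterError(f"year {year} outside [{lo}, {hi}]")
    return series.interpolate(year)


@dataclass(frozen=True)
class AdjustedWorld:
    """Scenario view of a world at one year: shifted hazard curves, lowered
    DEM, and exposure scale factors per region. The base world is never
    mutated."""

    year: float
    percentile: int
    scenario_name: str
    slr_offset: float
    transects: tuple          # hazard curves shifted by the SLR offset
    dem: np.ndarray           # subsided terrain
    damage_scale: dict        # region_id -> GDP growth factor
    pop_scale: dict           # region_id -> population growth factor


def apply_scenario(world, scenario, year: float,
                   percentile: int = 50) -> AdjustedWorld:
    """Pure scenario application; year 2020 returns the baseline unchanged
    (offset 0, all factors 1)."""
    lo, hi = YEAR_RANGE
    if not (lo <= year <= hi):
        raise ParameterError(f"year {year} outside [{lo}, {hi}]")
    if percentile not in (5, 50, 95):
        raise ParameterError("percentile must be one of 5, 50, 95")
    offset = scenario.slr_offset(year, percentile)
    dt = year - 2020
    dem = world.dem.copy()
    for r in world.regions:
        dem[r.row_slice[0]:r.row_slice[1], :] -= r.subsidence_rate * dt
    transects = tuple(
        replace(t, hazard=t.hazard.shifted(offset)) for t in world.transects)
    damage_scale = {r.id: scenario.gdp_factor(year, r.country_id)
                    for r in world.regions}
    pop_scale = {r.id: scenario.pop_factor(year, r.country_id)
                 for r in world.regions}
    return AdjustedWorld(year=year, percentile=percentile,
                         scenario_name=scenario.name, slr_offset=offset,
                         transects=transects, dem=dem,
                         damage_scale=damage_scale, pop_scale=pop_scale)
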