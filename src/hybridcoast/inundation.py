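"""Planar ("bathtub") coastal inundation with hydraulic connectivity.

Extreme sea levels force a flood fill from coastal seed cells.  A resistance
factor ``lam`` (m per km of along-path distance) attenuates the effective
water level inland, mimicking the limited duration of tides and surges; a
cell floods only if it is hydraulically connected to the coast through
already-flooded cells, so low-lying basins behind ridges stay dry.  Each
flooded cell also records the transect catchment through which the water
reached it.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

logger = logging.getLogger(__name__)

DEFAULT_LAM = 0.5  # m of head loss per km of flow path

# 8-neighbour offsets and step lengths in cell units
_NEIGHBOURS = [(-1, -1, np.sqrt(2)), (-1, 0, 1.0), (-1, 1, np.sqrt(2)),
               (0, -1, 1.0), (0, 1, 1.0),
               (1, -1, np.sqrt(2)), (1, 0, 1.0), (1, 1, np.sqrt(2))]


@dataclass
class DepthGrid:
    """Inundation depths [m] for one return period and year, with the
    transect catchment id of every flooded cell (-1 where dry)."""

    depth: np.ndarray
    catchment: np.ndarray
    return_period: float
    year: float = 2020.0
    scenario: str = "baseline"
    state: str = "current"

    @property
    def flooded(self) -> np.ndarray:
        return self.depth > 0.0


def planar_inundation(dem: np.ndarray, coastal_wl, lam: float,
                      seeds, cell_size_m: float = 1000.0,
                      seed_transects=None) -> DepthGrid:
    """Best-first flood fill maximising the attenuated head.

    ``seeds`` is a sequence of (row, col); ``coastal_wl`` is a scalar or one
    water level per seed. A cell at along-path distance d (km, diagonal
    steps count sqrt(2)) floods iff dem < wl - lam*d, with depth
    wl - lam*d - dem; propagation continues only through flooded cells.
    """
    if lam < 0:
        raise ParameterError("lam must be >= 0")
    seeds = list(seeds)
    if not seeds:
        raise ParameterError("seed set must not be empty")
    dem = np.asarray(dem, dtype=float)
    ny, nx = dem.shape
    wls = np.broadcast_to(np.asarray(coastal_wl, dtype=float), (len(seeds),))
    tids = (np.broadcast_to(np.asarray(seed_transects), (len(seeds),))
            if seed_transects is not None else np.full(len(seeds), -1))
    cell_km = cell_size_m / 1000.0

    head = np.full((ny, nx), -np.inf)
    catch = np.full((ny, nx), -1, dtype=int)
    heap = []
    for (r, c), wl, tid in zip(seeds, wls, tids):
        if wl > head[r, c]:
            head[r, c] = wl
            catch[r, c] = int(tid)
            heapq.heappush(heap, (-wl, r, c, int(tid)))
    while heap:
        negh, r, c, tid = heapq.heappop(heap)
        h = -negh
        if h < head[r, c] - 1e-12:
            continue  # stale entry
        if dem[r, c] >= h:
            continue  # not flooded: water does not pass through
        for dr, dc, step in _NEIGHBOURS:
            rr, cc = r + dr, c + dc
            if not (0 <= rr < ny and 0 <= cc < nx):
                continue
            h2 = h - lam * step * cell_km
            if h2 > head[rr, cc] + 1e-12:
                head[rr, cc] = h2
                catch[rr, cc] = tid
                heapq.heappush(heap, (-h2, rr, cc, tid))
    depth = np.where(head > dem, head - dem, 0.0)
    catch[depth <= 0] = -1
    return DepthGrid(depth=depth, catchment=catch, return_period=0.0)


def transect_catchments(world) -> np.ndarray:
    """Nearest-anchor assignment of coastal (first-column) cells to
    transects: returns the transect id per coastal row."""
    c = world.config.cell_size_m
    rows_y = (np.arange(world.config.ny) + 0.5) * c
    anchors = np.array([t.anchor_y for t in world.transects])
    ids = np.array([t.id for t in world.transects])
    return ids[np.argmin(np.abs(rows_y[:, None] - anchors[None, :]), axis=1)]


def hazard_stack(world, adjusted, protection_by_transect: dict | None = None,
                 lam: float = DEFAULT_LAM, state: str = "current",
                 return_periods=None) -> dict:
    """One :class:`DepthGrid` per return period under protection truncation.

    A transect's catchment floods at return period T only if T strictly
    exceeds that transect's effective protection level; the coastal water
    level is the transect's scenario-adjusted WL(T); the DEM is the subsided
    terrain.  ``protection_by_transect=None`` means undefended (everything
    floods).
    """
    catch_rows = transect_catchments(world)
    tr_by_id = {t.id: t for t in adjusted.transects}
    rps = (return_periods if return_periods is not None
           else world.transects[0].hazard.return_periods)
    stacks = {}
    for T in rps:
        seeds, wls, tids = [], [], []
        for row, tid in enumerate(catch_rows):
            if protection_by_transect is not None:
                prot = protection_by_transect.get(tid)
                if prot is None:
                    logger.warning("transect %s missing protection level; "
                                   "defaulting to 2 y", tid)
                    prot = 2.0
                if T <= prot:
                    continue
            seeds.append((row, 0))
            wls.append(tr_by_id[tid].hazard.wl(T))
            tids.append(tid)
        if seeds:
            grid = planar_inundation(adjusted.dem, np.array(wls), lam, seeds,
                                     cell_size_m=world.config.cell_size_m,
                                     seed_transects=np.array(tids))
        else:
            grid = DepthGrid(depth=np.zeros(world.shape),
                             catchment=np.full(world.shape, -1, dtype=int),
                             return_period=float(T))
        grid.return_period = float(T)
        grid.year = adjusted.year
        grid.scenario = adjusted.scenario_name
        grid.state = state
        stacks[float(T)] = grid
    return stacks
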