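"""Seeded synthetic coastal worlds.

Every external dataset the assessment would normally consume — extreme sea
levels, offshore wave climate, a coastal DEM, built-up/population/GDP grids,
mangrove extents, administrative protection attributes, wealth and poverty
grids, and climate/socioeconomic scenarios — is emulated here with the
statistical structure the downstream analysis assumes:

* extreme still-water levels follow a Gumbel-type curve WL(T) = mu + beta ln T
  per transect, offshore Hs grows logarithmically with T anchored at the
  100-y value;
* the DEM rises inland from a low coastal strip, so coastal cells sit below
  inland cells on average;
* built-up fraction and population decay with distance to the coast;
* the wealth index is normal around the country mean (0) with a configurable
  monotone trend versus distance to coast (a positive inland trend encodes a
  negative wealth-exposure correlation), and poverty likelihood is a logistic
  transform of wealth so the two indicators stay coherent.

The same (config, seed) pair always regenerates a bit-identical world.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import xarray as xr

from .errors import ConfigurationError, ParameterError
from .foreshore import HazardCurve, Transect

#: the nine simulated return periods [y]
RETURN_PERIODS = np.array([2.0, 5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0,
                           1000.0])
NODATA = -9999.0
INCOME_GROUPS = ("low", "lower-middle", "upper-middle", "high")

#: GDP per capita [currency/person/yr] by income group
GDP_PC_BY_INCOME = {"low": 1500.0, "lower-middle": 5000.0,
                    "upper-middle": 14000.0, "high": 42000.0}
#: baseline poverty probability by income group (logistic intercept)
POVERTY_BASE = {"low": 0.60, "lower-middle": 0.40, "upper-middle": 0.15,
                "high": 0.05}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class WorldConfig:
    """Knobs of the synthetic world; defaults give a minute-scale toy world."""

    nx: int = 200
    ny: int = 200
    cell_size_m: float = 1000.0
    n_transects: int = 40
    n_regions: int = 4
    n_countries: int = 2
    # hazard (Gumbel-type) parameter ranges
    gumbel_mu_range: tuple = (1.0, 2.0)
    gumbel_beta_range: tuple = (0.2, 0.45)
    hs100_range: tuple = (1.5, 3.0)
    # transect geometry
    transect_length_m: float = 4000.0
    offshore_depth_range: tuple = (5.0, 9.0)
    # mangroves [m]
    current_width_range: tuple = (50.0, 500.0)
    current_width_fraction: float = 0.4
    restorable_width_range: tuple = (50.0, 400.0)
    restorable_fraction: float = 0.6
    # terrain
    coast_elev_range: tuple = (0.0, 1.5)
    inland_slope_m_per_km: float = 0.8
    dem_noise_sd: float = 0.3
    # exposure
    builtup_coastal_peak: float = 0.45
    builtup_decay_km: float = 12.0
    pop_density_per_builtup_km2: float = 4000.0
    # wealth / poverty
    wealth_sd: float = 1.0
    wealth_trend_per_km: float = 0.01  # > 0: wealth rises inland
    wealth_exposure_correlation: str = "negative"
    poverty_slope: float = 1.5
    # economics
    implementation_cost_median: float = 8143.0  # currency per hectare
    implementation_cost_sigma: float = 1.0      # lognormal spread
    implementation_cost_range: tuple = (27.0, 253300.0)

    def validate(self) -> None:
        for fld in ("nx", "ny", "n_transects", "n_regions", "n_countries"):
            if getattr(self, fld) <= 0:
                raise ConfigurationError(f"{fld} must be > 0")
        for fld in ("cell_size_m", "transect_length_m",
                    "pop_density_per_builtup_km2", "builtup_decay_km",
                    "implementation_cost_median"):
            if getattr(self, fld) <= 0:
                raise ConfigurationError(f"{fld} must be > 0")
        for fld in ("current_width_fraction", "restorable_fraction",
                    "builtup_coastal_peak"):
            v = getattr(self, fld)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{fld} must be within [0, 1]")
        for fld in ("gumbel_mu_range", "gumbel_beta_range", "hs100_range",
                    "offshore_depth_range", "current_width_range",
                    "restorable_width_range", "coast_elev_range"):
            lo, hi = getattr(self, fld)
            if lo > hi:
                raise ConfigurationError(f"{fld} has lo > hi")
        if self.gumbel_beta_range[0] <= 0:
            raise ConfigurationError("gumbel_beta_range must be positive")
        if self.hs100_range[0] <= 0:
            raise ConfigurationError("hs100_range must be positive")
        if self.wealth_exposure_correlation not in ("negative", "positive"):
            raise ConfigurationError(
                "wealth_exposure_correlation must be 'negative' or 'positive'")
        if self.n_regions < self.n_countries:
            raise ConfigurationError("n_regions must be >= n_countries")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class AdminRegion:
    """Subnational unit: an alongshore band of the grid with FLOPROS-style
    attributes and a restoration cost level."""

    id: int
    country_id: int
    income_group: str
    urbanization: float
    row_slice: tuple  # (start, stop) rows of the raster band
    implementation_cost_per_ha: float = 8143.0
    subsidence_rate: float = 0.0  # m/yr (positive down)

    def mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.row_slice[0]:self.row_slice[1], :] = True
        return m


@dataclass
class ScenarioSpec:
    """RCP/SSP combination: sea-level offsets by epoch and percentile plus
    country-level growth rates."""

    rcp: str
    ssp: str
    #: {epoch: {percentile: offset m}}; 2020 offset is 0 by construction
    slr_offsets: dict
    gdp_growth_rate: dict   # country_id -> annual rate
    pop_growth_rate: dict   # country_id -> annual rate

    @property
    def name(self) -> str:
        return f"{self.rcp}_{self.ssp}"

    def __post_init__(self):
        epochs = sorted(self.slr_offsets)
        if epochs[0] != 2020 or any(abs(v) > 1e-12
                                    for v in self.slr_offsets[2020].values()):
            raise ConfigurationError("slr_offsets: 2020 offset must be 0")
        for pct in (5, 50, 95):
            series = [self.slr_offsets[e][pct] for e in epochs]
            if any(v < 0 for v in series) or any(np.diff(series) < 0):
                raise ConfigurationError(
                    "slr_offsets must be nonnegative, nondecreasing in epoch")

    def slr_offset(self, year: float, percentile: int = 50) -> float:
        """Offset interpolated to ``year`` (piecewise linear between epochs,
        2050-2080 slope extrapolated beyond 2080, floored at 0)."""
        from .scenarios import EpochSeries  # local import avoids a cycle
        epochs = sorted(self.slr_offsets)
        values = [self.slr_offsets[e][percentile] for e in epochs]
        return EpochSeries(tuple(epochs), tuple(values)).interpolate(year)

    def gdp_factor(self, year: float, country_id: int) -> float:
        return (1.0 + self.gdp_growth_rate[country_id]) ** (year - 2020)

    def pop_factor(self, year: float, country_id: int) -> float:
        return (1.0 + self.pop_growth_rate[country_id]) ** (year - 2020)


@dataclass
class SyntheticWorld:
    """Bundle of rasters, transects, regions and scenarios from one seed."""

    config: WorldConfig
    seed: int
    dem: np.ndarray          # m above MSL
    builtup: np.ndarray      # fraction [0, 1]
    population: np.ndarray   # persons per cell
    wealth: np.ndarray       # index, 0 = country mean
    poverty_p: np.ndarray    # probability [0, 1]
    transects: list = field(default_factory=list)
    regions: list = field(default_factory=list)
    scenarios: list = field(default_factory=list)

    @property
    def shape(self):
        return self.dem.shape

    @property
    def cell_area_km2(self) -> float:
        return (self.config.cell_size_m / 1000.0) ** 2

    @property
    def geotransform(self):
        # (x origin, pixel width, 0, y origin, 0, -pixel height); coast at x=0
        c = self.config.cell_size_m
        return (0.0, c, 0.0, self.config.ny * c, 0.0, -c)

    def gdp_pc(self, region_id: int) -> float:
        return GDP_PC_BY_INCOME[self.regions[region_id].income_group]

    def region_of_row(self, row: int) -> AdminRegion:
        for r in self.regions:
            if r.row_slice[0] <= row < r.row_slice[1]:
                return r
        raise ParameterError(f"row {row} outside all regions")

    def scenario(self, name: str) -> ScenarioSpec:
        for s in self.scenarios:
            if s.name == name:
                return s
        raise ConfigurationError(f"unknown scenario {name!r}")

    def validate(self) -> None:
        shp = self.dem.shape
        for name in ("builtup", "population", "wealth", "poverty_p"):
            if getattr(self, name).shape != shp:
                raise ConfigurationError(f"raster {name} shape mismatch")
        if self.builtup.min() < 0 or self.builtup.max() > 1:
            raise ConfigurationError("builtup outside [0, 1]")
        if self.poverty_p.min() < 0 or self.poverty_p.max() > 1:
            raise ConfigurationError("poverty_p outside [0, 1]")
        if self.population.min() < 0:
            raise ConfigurationError("population must be >= 0")
        covered = np.zeros(shp, dtype=bool)
        for r in self.regions:
            m = r.mask(shp)
            if (covered & m).any():
                raise ConfigurationError("region masks overlap")
            covered |= m
        if not covered.all():
            raise ConfigurationError("region masks do not cover the grid")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_hazard_curve(mu: float, beta: float, hs100: float,
                          return_periods=RETURN_PERIODS) -> HazardCurve:
    """Gumbel-type water-level curve WL(T) = mu + beta ln T with offshore
    Hs(T) = hs100 (1 + 0.15 ln(T/100)), floored at 0.2 hs100."""
    if beta <= 0:
        raise ParameterError("beta must be > 0")
    if hs100 <= 0:
        raise ParameterError("hs100 must be > 0")
    rp = np.asarray(return_periods, dtype=float)
    if rp.size == 0 or np.any(rp < 1) or np.any(np.diff(rp) <= 0):
        raise ParameterError("return periods must be strictly increasing, >= 1")
    wl = mu + beta * np.log(rp)
    hs = np.maximum(hs100 * (1.0 + 0.15 * np.log(rp / 100.0)), 0.2 * hs100)
    return HazardCurve(rp, wl, hs)


def _make_regions(config: WorldConfig, rng: np.random.Generator) -> list:
    bounds = np.linspace(0, config.ny, config.n_regions + 1).astype(int)
    groups = rng.choice(len(INCOME_GROUPS), size=config.n_regions)
    regions = []
    for i in range(config.n_regions):
        country = i * config.n_countries // config.n_regions
        ic = float(np.clip(
            np.exp(rng.normal(np.log(config.implementation_cost_median),
                              config.implementation_cost_sigma)),
            *config.implementation_cost_range))
        regions.append(AdminRegion(
            id=i, country_id=int(country),
            income_group=INCOME_GROUPS[int(groups[i])],
            urbanization=float(rng.uniform(0.1, 0.9)),
            row_slice=(int(bounds[i]), int(bounds[i + 1])),
            implementation_cost_per_ha=ic,
            subsidence_rate=float(rng.uniform(0.0, 0.006))))
    return regions


def _make_scenarios(config: WorldConfig, rng: np.random.Generator) -> list:
    countries = range(config.n_countries)
    # fixed epoch offsets; the stronger forcing pathway dominates by epoch
    rcp45 = {2020: {5: 0.0, 50: 0.0, 95: 0.0},
             2050: {5: 0.10, 50: 0.18, 95: 0.28},
             2080: {5: 0.25, 50: 0.42, 95: 0.65}}
    rcp85 = {2020: {5: 0.0, 50: 0.0, 95: 0.0},
             2050: {5: 0.12, 50: 0.22, 95: 0.35},
             2080: {5: 0.35, 50: 0.60, 95: 0.90}}
    g2 = {c: float(rng.uniform(0.015, 0.025)) for c in countries}
    g5 = {c: g2[c] + float(rng.uniform(0.005, 0.012)) for c in countries}
    p2 = {c: float(rng.uniform(0.005, 0.012)) for c in countries}
    p5 = {c: p2[c] + float(rng.uniform(0.002, 0.006)) for c in countries}
    return [ScenarioSpec("RCP45", "SSP2", rcp45, g2, p2),
            ScenarioSpec("RCP85", "SSP5", rcp85, g5, p5)]


def _make_transects(config: WorldConfig, regions: list,
                    rng: np.random.Generator, dem: np.ndarray) -> list:
    c = config.cell_size_m
    spacing = config.ny * c / config.n_transects
    transects = []
    for i in range(config.n_transects):
        y = (i + 0.5) * spacing
        row = min(int(y // c), config.ny - 1)
        region = next(r for r in regions if r.row_slice[0] <= row < r.row_slice[1])
        depth = rng.uniform(*config.offshore_depth_range)
        coast_elev = max(float(dem[row, 0]), 0.2)
        length = config.transect_length_m
        ch = np.array([0.0, length])
        el = np.array([-depth, coast_elev])
        mu = rng.uniform(*config.gumbel_mu_range)
        beta = rng.uniform(*config.gumbel_beta_range)
        hs100 = rng.uniform(*config.hs100_range)
        cur = (rng.uniform(*config.current_width_range)
               if rng.random() < config.current_width_fraction else 0.0)
        raw = (rng.uniform(*config.restorable_width_range)
               if rng.random() < config.restorable_fraction else 0.0)
        transects.append(Transect(
            id=i, anchor_x=0.0, anchor_y=float(y), bearing_deg=270.0,
            profile_chainage=ch, profile_elevation=el,
            mangrove_width_current=float(cur),
            mangrove_width_restorable=float(raw),
            region_id=region.id,
            hazard=generate_hazard_curve(mu, beta, hs100),
            restorable_raw=float(raw)))
    return transects


def generate_world(config: WorldConfig | None = None,
                   seed: int = 0) -> SyntheticWorld:
    """Generate a synthetic coastal world. Deterministic in (config, seed)."""
    config = config or WorldConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    ny, nx = config.ny, config.nx
    cell_km = config.cell_size_m / 1000.0
    dist_km = (np.arange(nx) + 0.5) * cell_km  # distance to coast per column
    dist2d = np.broadcast_to(dist_km, (ny, nx))

    coast_elev = rng.uniform(*config.coast_elev_range, size=(ny, 1))
    dem = (coast_elev + config.inland_slope_m_per_km * dist2d
           + rng.normal(0.0, config.dem_noise_sd, size=(ny, nx)))

    builtup = np.clip(
        config.builtup_coastal_peak * np.exp(-dist2d / config.builtup_decay_km)
        * rng.lognormal(0.0, 0.6, size=(ny, nx)), 0.0, 1.0)
    builtup[rng.random((ny, nx)) < 0.25] = 0.0  # empty cells
    cell_area = cell_km ** 2
    population = np.round(builtup * config.pop_density_per_builtup_km2
                          * cell_area * rng.lognormal(0.0, 0.4, size=(ny, nx)))

    trend = config.wealth_trend_per_km
    if config.wealth_exposure_correlation == "positive":
        trend = -trend
    wealth = rng.normal(0.0, config.wealth_sd, size=(ny, nx)) + trend * dist2d

    regions = _make_regions(config, rng)
    scenarios = _make_scenarios(config, rng)
    transects = _make_transects(config, regions, rng, dem)
    if not any(t.restorable_raw > 0 for t in transects):
        raise ConfigurationError(
            "restorable_fraction too low: no restorable transects generated")

    # centre wealth per country, then map to poverty likelihood
    poverty_p = np.empty_like(wealth)
    for country in range(config.n_countries):
        rows = np.zeros(ny, dtype=bool)
        base = []
        for r in regions:
            if r.country_id == country:
                rows[r.row_slice[0]:r.row_slice[1]] = True
                base.append(POVERTY_BASE[r.income_group])
        wealth[rows] -= wealth[rows].mean()
        p0 = float(np.mean(base))
        logit0 = np.log(p0 / (1.0 - p0))
        z = logit0 - config.poverty_slope * wealth[rows]
        poverty_p[rows] = 1.0 / (1.0 + np.exp(-z))

    world = SyntheticWorld(config=config, seed=seed, dem=dem, builtup=builtup,
                           population=population, wealth=wealth,
                           poverty_p=poverty_p, transects=transects,
                           regions=regions, scenarios=scenarios)
    world.validate()
    return world


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_raster(path: Path, arr: np.ndarray) -> None:
    tifffile.imwrite(path, arr.astype(np.float32))


def _transects_geojson(transects) -> dict:
    feats = []
    for t in transects:
        feats.append({
            "type": "Feature",
            "geometry": {"type": "LineString",
                         "coordinates": [[t.anchor_x - t.length, t.anchor_y],
                                         [t.anchor_x, t.anchor_y]]},
            "properties": {
                "id": t.id, "anchor_x": t.anchor_x, "anchor_y": t.anchor_y,
                "bearing_deg": t.bearing_deg, "region_id": t.region_id,
                "mangrove_width_current": t.mangrove_width_current,
                "mangrove_width_restorable": t.mangrove_width_restorable,
                "restorable_raw": t.restorable_raw,
                "profile_chainage": list(map(float, t.profile_chainage)),
                "profile_elevation": list(map(float, t.profile_elevation)),
            }})
    return {"type": "FeatureCollection", "features": feats}


def write_fixtures(world: SyntheticWorld, outdir) -> dict:
    """Serialise a world to disk; returns {filename: sha256} manifest.

    Rasters go to single-band float32 TIFF (nodata -9999 recorded in the
    manifest), transects to GeoJSON, hazard curves to NetCDF, regions and
    scenarios to CSV/JSON.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {outdir}: {exc}")
    files = {}
    for name in ("dem", "builtup", "population", "wealth", "poverty_p"):
        path = outdir / f"{name}.tif"
        _write_raster(path, getattr(world, name))
        files[path.name] = _sha256(path)

    gj = outdir / "transects.geojson"
    gj.write_text(json.dumps(_transects_geojson(world.transects), indent=1,
                             sort_keys=True))
    files[gj.name] = _sha256(gj)

    hz = xr.Dataset(
        {"water_level": (("transect", "return_period"),
                         np.stack([t.hazard.water_level for t in world.transects])),
         "hs": (("transect", "return_period"),
                np.stack([t.hazard.hs_offshore for t in world.transects]))},
        coords={"transect": [t.id for t in world.transects],
                "return_period": world.transects[0].hazard.return_periods})
    nc = outdir / "hazard.nc"
    hz.to_netcdf(nc, engine="scipy")
    files[nc.name] = _sha256(nc)

    reg = pd.DataFrame([{
        "id": r.id, "country_id": r.country_id, "income_group": r.income_group,
        "urbanization": r.urbanization, "row_start": r.row_slice[0],
        "row_stop": r.row_slice[1],
        "implementation_cost_per_ha": r.implementation_cost_per_ha,
        "subsidence_rate": r.subsidence_rate} for r in world.regions])
    rc = outdir / "regions.csv"
    reg.to_csv(rc, index=False, float_format="%.17g")
    files[rc.name] = _sha256(rc)

    sc = outdir / "scenarios.json"
    sc.write_text(json.dumps([{
        "rcp": s.rcp, "ssp": s.ssp,
        "slr_offsets": {str(e): {str(p): v for p, v in d.items()}
                        for e, d in s.slr_offsets.items()},
        "gdp_growth_rate": {str(k): v for k, v in s.gdp_growth_rate.items()},
        "pop_growth_rate": {str(k): v for k, v in s.pop_growth_rate.items()},
    } for s in world.scenarios], indent=1, sort_keys=True))
    files[sc.name] = _sha256(sc)

    meta = outdir / "world.json"
    meta.write_text(json.dumps({"seed": world.seed, "nodata": NODATA,
                                "geotransform": list(world.geotransform),
                                "config": asdict(world.config)},
                               indent=1, sort_keys=True))
    files[meta.name] = _sha256(meta)

    manifest = outdir / "manifest.json"
    manifest.write_text(json.dumps(files, indent=1, sort_keys=True))
    return files


def read_fixtures(outdir) -> SyntheticWorld:
    """Round-trip loader for :func:`write_fixtures` output."""
    outdir = Path(outdir)
    meta = json.loads((outdir / "world.json").read_text())
    cfg_dict = meta["config"]
    for key in ("gumbel_mu_range", "gumbel_beta_range", "hs100_range",
                "offshore_depth_range", "current_width_range",
                "restorable_width_range", "coast_elev_range",
                "implementation_cost_range"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = WorldConfig(**cfg_dict)
    rasters = {name: tifffile.imread(outdir / f"{name}.tif").astype(float)
               for name in ("dem", "builtup", "population", "wealth",
                            "poverty_p")}
    reg = pd.read_csv(outdir / "regions.csv", float_precision="round_trip")
    regions = [AdminRegion(id=int(r.id), country_id=int(r.country_id),
                           income_group=r.income_group,
                           urbanization=float(r.urbanization),
                           row_slice=(int(r.row_start), int(r.row_stop)),
                           implementation_cost_per_ha=float(
                               r.implementation_cost_per_ha),
                           subsidence_rate=float(r.subsidence_rate))
               for r in reg.itertuples()]
    scenarios = []
    for s in json.loads((outdir / "scenarios.json").read_text()):
        scenarios.append(ScenarioSpec(
            rcp=s["rcp"], ssp=s["ssp"],
            slr_offsets={int(e): {int(p): v for p, v in d.items()}
                         for e, d in s["slr_offsets"].items()},
            gdp_growth_rate={int(k): v for k, v in s["gdp_growth_rate"].items()},
            pop_growth_rate={int(k): v for k, v in s["pop_growth_rate"].items()}))
    hz = xr.open_dataset(outdir / "hazard.nc", engine="scipy")
    rp = hz["return_period"].values.astype(float)
    transects = []
    for feat in json.loads((outdir / "transects.geojson").read_text())["features"]:
        p = feat["properties"]
        i = int(p["id"])
        transects.append(Transect(
            id=i, anchor_x=float(p["anchor_x"]), anchor_y=float(p["anchor_y"]),
            bearing_deg=float(p["bearing_deg"]),
            profile_chainage=np.array(p["profile_chainage"]),
            profile_elevation=np.array(p["profile_elevation"]),
            mangrove_width_current=float(p["mangrove_width_current"]),
            mangrove_width_restorable=float(p["mangrove_width_restorable"]),
            region_id=int(p["region_id"]),
            hazard=HazardCurve(rp, hz["water_level"].sel(transect=i).values,
                               hz["hs"].sel(transect=i).values),
            restorable_raw=float(p["restorable_raw"])))
    hz.close()
    world = SyntheticWorld(config=config, seed=int(meta["seed"]),
                           dem=rasters["dem"], builtup=rasters["builtup"],
                           population=rasters["population"],
                           wealth=rasters["wealth"],
                           poverty_p=rasters["poverty_p"],
                           transects=transects, regions=regions,
                           scenarios=scenarios)
    world.validate()
    return world


def worlds_equal(a: SyntheticWorld, b: SyntheticWorld,
                 atol: float = 1e-6) -> bool:
    """Structural equality up to float32 round-trip of the rasters."""
    for name in ("dem", "builtup", "population", "wealth", "poverty_p"):
        if not np.allclose(getattr(a, name), getattr(b, name), atol=atol):
            return False
    if len(a.transects) != len(b.transects):
        return False
    for ta, tb in zip(a.transects, b.transects):
        if ta.id != tb.id or ta.region_id != tb.region_id:
            return False
        if not (np.allclose(ta.profile_elevation, tb.profile_elevation)
                and np.allclose(ta.hazard.water_level, tb.hazard.water_level)
                and np.allclose(ta.hazard.hs_offshore, tb.hazard.hs_offshore)
                and abs(ta.mangrove_width_current - tb.mangrove_width_current) < atol
                and abs(ta.mangrove_width_restorable
                        - tb.mangrove_width_restorable) < atol):
            return False
    return a.regions == b.regions and len(a.scenarios) == len(b.scenarios)
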