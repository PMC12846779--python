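"""End-to-end orchestration: world -> attenuation -> dike design ->
inundation -> risk -> scenarios -> benefit-cost -> equity.

``run_pipeline`` executes the stages in dependency order from a single
validated configuration, writes per-region outputs as CSV, and records a
manifest (config hash, seed, per-file checksums, wall time per stage) so a
rerun with the same config and seed reproduces identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .defense import (DikeSpec, design_crest, effective_protection,
                      flopros_standard)
from .economics import (DISCOUNT_RATES, MIN_AREA_HA, SURVIVAL_RATES,
                        aggregate_regions, region_bca, sensitivity_grid)
from .equity import (FLOOD_PRONE_RP, RESAMPLE_BUDGET, group_masks,
                     mann_whitney, poverty_table, wealth_distribution,
                     weighted_sample)
from .errors import ConfigurationError, DependencyError
from .foreshore import assign_restorable_width, transect_nearshore_hs
from .inundation import DEFAULT_LAM, hazard_stack
from .risk import (RiskCurve, build_max_damages, cell_impact, eaap,
                   expected_annual, restoration_benefit)
from .scenarios import EPOCHS, EpochSeries, apply_scenario, epoch_interpolate
from .synthetic_world import (SyntheticWorld, WorldConfig, generate_world,
                              write_fixtures)

logger = logging.getLogger(__name__)

_RUN_KEYS = {"world", "scenario", "percentile", "lam", "flood_prone_rp",
             "discount_rate", "survival_rate", "include_opportunity",
             "sensitivity", "min_area_ha", "seed", "outdir"}


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys are rejected)."""

    world: WorldConfig = field(default_factory=WorldConfig)
    scenario: str = "RCP45_SSP2"
    percentile: int = 50
    lam: float = DEFAULT_LAM
    flood_prone_rp: float = FLOOD_PRONE_RP
    discount_rate: float = 0.05
    survival_rate: float = 0.75
    include_opportunity: bool = True
    sensitivity: bool = True
    min_area_ha: float = MIN_AREA_HA
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        self.world.validate()
        if self.percentile not in (5, 50, 95):
            raise ConfigurationError("percentile must be one of 5, 50, 95")
        if self.lam < 0:
            raise ConfigurationError("lam must be >= 0")
        if not (0 < self.survival_rate < 1):
            raise ConfigurationError("survival_rate must be in (0, 1)")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        unknown = set(data) - _RUN_KEYS
        if unknown:
            raise ConfigurationError(
                f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        wdata = data.pop("world", {})
        wfields = {f.name for f in dataclasses.fields(WorldConfig)}
        bad = set(wdata) - wfields
        if bad:
            raise ConfigurationError(f"unknown world config keys: {sorted(bad)}")
        for key in wfields & set(wdata):
            if isinstance(wdata[key], list):
                wdata[key] = tuple(wdata[key])
        cfg = cls(world=WorldConfig(**wdata), **data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir", None)  # where outputs land is not part of what
        return hashlib.sha256(json.dumps(payload, sort_keys=True,
                                         default=str).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    checksums: dict = field(default_factory=dict)
    wall_times: dict = field(default_factory=dict)


@dataclass
class PipelineResult:
    world: SyntheticWorld
    attenuation: pd.DataFrame
    protection: pd.DataFrame
    transect_risk: pd.DataFrame
    region_risk: pd.DataFrame
    bca: pd.DataFrame
    sensitivity: pd.DataFrame | None
    excluded_regions: list
    equity_table: pd.DataFrame
    wealth_hists: pd.DataFrame
    rank_tests: pd.DataFrame
    manifest: RunManifest


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Stages:
    """Incremental pipeline state; each method is one stage."""

    def __init__(self, config: RunConfig):
        config.validate()
        self.cfg = config
        self.manifest = RunManifest(config_hash=config.hash(),
                                    seed=config.seed, version=__version__)
        self._t = {}

    def _tick(self, stage):
        self._t[stage] = time.perf_counter()

    def _tock(self, stage):
        self.manifest.wall_times[stage] = round(
            time.perf_counter() - self._t[stage], 3)

    # -- stage 1: synthetic world -------------------------------------
    def world(self):
        self._tick("world")
        self.w = generate_world(self.cfg.world, self.cfg.seed)
        self.scenario = self.w.scenario(self.cfg.scenario)
        self._tock("world")
        return self.w

    # -- stage 2: wave attenuation per transect and return period -----
    def attenuation(self):
        self._tick("attenuation")
        rows = []
        for t in self.w.transects:
            for T in t.hazard.return_periods:
                swl = t.hazard.wl(T)
                for state in ("current", "restored"):
                    hs = transect_nearshore_hs(t, swl, t.hazard.hs(T),
                                               t.veg_width(state))
                    rows.append({"transect": t.id, "return_period": T,
                                 "state": state, "swl": swl,
                                 "hs_offshore": t.hazard.hs(T),
                                 "hs_nearshore": hs})
        self.attenuation_df = pd.DataFrame(rows)
        self._tock("attenuation")
        return self.attenuation_df

    # -- stage 3: dike design and effective protection levels ---------
    def design(self):
        self._tick("design")
        self.standards, self.dikes = {}, {}
        for t in self.w.transects:
            region = self.w.regions[t.region_id]
            std = flopros_standard(region.income_group, region.urbanization)
            self.standards[t.id] = std
            self.dikes[t.id] = design_crest(t, std, "current")
        # protection per epoch for the current state (restored comes after
        # the restorable widths are buffered in stage 5)
        self.protection = {"current": self._protection_by_epoch("current",
                                                                self.w.transects)}
        self._tock("design")
        return self.dikes

    def _protection_by_epoch(self, state, transects):
        out = {}
        for epoch in EPOCHS:
            per = {}
            for t in transects:
                per[t.id] = effective_protection(
                    t, self.dikes[t.id], state, year=epoch,
                    scenario=self.scenario, percentile=self.cfg.percentile)
            out[epoch] = per
        return out

    # -- stage 4: inundation + per-transect risk curves ---------------
    def risk_current(self):
        if not hasattr(self, "dikes"):
            raise DependencyError("risk stage requires the design stage")
        self._tick("risk")
        self.maxdam = build_max_damages(self.w)
        self.stacks = {}          # epoch -> {T: DepthGrid} (undefended)
        self.impact_by_transect = {}   # epoch -> {tid: array over T}
        self.exposed_by_transect = {}  # epoch -> {tid: array over T}
        rps = self.w.transects[0].hazard.return_periods
        for epoch in EPOCHS:
            adj = apply_scenario(self.w, self.scenario, epoch,
                                 self.cfg.percentile)
            stack = hazard_stack(self.w, adj, None, lam=self.cfg.lam)
            self.stacks[epoch] = stack
            dmg_scale = np.ones(self.w.shape)
            pop_scale = np.ones(self.w.shape)
            for r in self.w.regions:
                sl = slice(r.row_slice[0], r.row_slice[1])
                dmg_scale[sl, :] = adj.damage_scale[r.id]
                pop_scale[sl, :] = adj.pop_scale[r.id]
            imp, exp_ = {}, {}
            for t in self.w.transects:
                imp[t.id] = np.zeros(rps.size)
                exp_[t.id] = np.zeros(rps.size)
            for k, T in enumerate(rps):
                grid = stack[float(T)]
                impact_map = cell_impact(grid.depth, self.maxdam) * dmg_scale
                pop_map = self.w.population * pop_scale
                for t in self.w.transects:
                    sel = grid.catchment == t.id
                    imp[t.id][k] = impact_map[sel].sum()
                    exp_[t.id][k] = pop_map[sel & grid.flooded].sum()
            self.impact_by_transect[epoch] = imp
            self.exposed_by_transect[epoch] = exp_
        self.ead = {"current": self._integrate("current")}
        self.eaap_ = {"current": self._integrate("current", people=True)}
        self._tock("risk")

    def _integrate(self, state, people=False):
        rps = self.w.transects[0].hazard.return_periods
        source = self.exposed_by_transect if people else self.impact_by_transect
        out = {}
        for epoch in EPOCHS:
            per = {}
            for t in self.w.transects:
                prot = self.protection[state][epoch][t.id]
                curve = RiskCurve.from_return_periods(
                    rps, source[epoch][t.id], protection_rp=prot)
                per[t.id] = expected_annual(curve)
            out[epoch] = per
        return out

    # -- stage 5: restorable widths + restored-state risk --------------
    def risk_restored(self):
        self._tick("restoration")
        at_risk = {t.region_id for t in self.w.transects
                   if self.ead["current"][2020][t.id] > 0
                   or self.eaap_["current"][2020][t.id] > 0}
        self.at_risk_regions = at_risk
        self.w.transects = assign_restorable_width(
            self.w.transects, radius=1000.0, at_risk_regions=at_risk)
        self.protection["restored"] = self._protection_by_epoch(
            "restored", self.w.transects)
        self.ead["restored"] = self._integrate("restored")
        self.eaap_["restored"] = self._integrate("restored", people=True)
        self._tock("restoration")

    # -- stage 6: benefit-cost analysis --------------------------------
    def economics(self):
        self._tick("economics")
        span_m = (self.cfg.world.ny * self.cfg.world.cell_size_m
                  / self.cfg.world.n_transects)
        areas, benefits, t_region = {}, {}, {}
        for t in self.w.transects:
            areas[t.id] = t.mangrove_width_restorable * span_m / 1e4
            t_region[t.id] = t.region_id
            series = EpochSeries(EPOCHS, tuple(
                restoration_benefit(self.ead["current"][e][t.id],
                                    self.ead["restored"][e][t.id])
                for e in EPOCHS))
            benefits[t.id] = (lambda year, _s=series:
                              epoch_interpolate(_s, year))
        region_meta = {}
        for r in self.w.regions:
            region_meta[r.id] = (
                r.country_id, r.implementation_cost_per_ha,
                (lambda year, _c=r.country_id:
                 self.scenario.gdp_factor(year, _c)))
        agg = aggregate_regions(areas, benefits, t_region, region_meta,
                                min_area_ha=self.cfg.min_area_ha)
        self.excluded_regions = agg.excluded
        self.region_econ = agg.retained
        rows = []
        for reg in agg.retained:
            res = region_bca(reg, r=self.cfg.discount_rate,
                             s=self.cfg.survival_rate,
                             include_opportunity=self.cfg.include_opportunity)
            rows.append({"region": reg.region_id, "country": reg.country_id,
                         "area_ha": reg.area_ha,
                         "disc_benefits": res.disc_benefits,
                         "disc_costs": res.disc_costs, "bcr": res.bcr,
                         "npv": res.npv, "r": res.discount_rate,
                         "s": res.survival_rate,
                         "opportunity": res.include_opportunity})
        self.bca_df = pd.DataFrame(rows)
        self.sens_df = (sensitivity_grid(agg.retained)
                        if self.cfg.sensitivity else None)
        self._tock("economics")

    # -- stage 7: equity ------------------------------------------------
    def equity(self):
        self._tick("equity")
        extent = self.stacks[2020][float(self.cfg.flood_prone_rp)]
        benefit_tids = [
            t.id for t in self.w.transects
            if t.mangrove_width_restorable > 0 and any(
                restoration_benefit(self.ead["current"][e][t.id],
                                    self.ead["restored"][e][t.id]) > 0
                for e in EPOCHS)]
        self.groups = group_masks(extent, benefit_tids, extent.catchment,
                                  self.w.population)
        pops = {c: self.scenario.pop_factor(2050, c)
                for c in range(self.cfg.world.n_countries)}
        growth = float(np.mean(list(pops.values())))
        self.equity_df = poverty_table(self.w.population, self.w.poverty_p,
                                       self.groups, growth_to_2050=growth)
        bins = np.linspace(self.w.wealth.min() - 0.25,
                           self.w.wealth.max() + 0.25, 41)
        hist_rows = []
        for name, mask in self.groups.items():
            edges, dens = wealth_distribution(self.w.wealth,
                                              self.w.population, mask, bins)
            for lo, hi, d in zip(edges[:-1], edges[1:], dens):
                hist_rows.append({"group": name, "bin_lo": lo, "bin_hi": hi,
                                  "density": d})
        self.wealth_df = pd.DataFrame(hist_rows)
        rng = np.random.default_rng(self.cfg.seed + 10007)
        samples = {name: weighted_sample(self.w.wealth, self.w.population,
                                         mask, rng, RESAMPLE_BUDGET)
                   for name, mask in self.groups.items()}
        tests = []
        for a, b in (("outside", "flood_prone"), ("outside", "benefit")):
            if samples[a].size and samples[b].size:
                res = mann_whitney(samples[a], samples[b])
                tests.append({"pair": f"{a}_vs_{b}", "U1": res.U1,
                              "U2": res.U2, "z": res.z, "p": res.p,
                              "n1": res.n1, "n2": res.n2,
                              "mean_a": float(samples[a].mean()),
                              "mean_b": float(samples[b].mean())})
        self.tests_df = pd.DataFrame(tests)
        self._tock("equity")

    # -- outputs ---------------------------------------------------------
    def write_outputs(self):
        if self.cfg.outdir is None:
            return
        out = Path(self.cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        self._tick("write")
        files = write_fixtures(self.w, out / "world")
        for name, sha in files.items():
            self.manifest.checksums[f"world/{name}"] = sha
        prot_rows = []
        for state, by_epoch in self.protection.items():
            for epoch, per in by_epoch.items():
                for tid, rp in per.items():
                    prot_rows.append({"transect": tid, "state": state,
                                      "year": epoch, "protection_rp": rp,
                                      "crest": self.dikes[tid].crest_elevation})
        tables = {
            "attenuation.csv": self.attenuation_df,
            "protection.csv": pd.DataFrame(prot_rows),
            "transect_risk.csv": self.transect_risk_df(),
            "region_risk.csv": self.region_risk_df(),
            "bca.csv": self.bca_df,
            "equity_table.csv": self.equity_df,
            "wealth_hist.csv": self.wealth_df,
            "rank_tests.csv": self.tests_df,
        }
        if self.sens_df is not None:
            tables["sensitivity.csv"] = self.sens_df
        for name, df in tables.items():
            path = out / name
            df.to_csv(path, index=False, float_format="%.10g")
            self.manifest.checksums[name] = _sha256(path)
        self._tock("write")
        mpath = out / "manifest.json"
        mpath.write_text(json.dumps(asdict(self.manifest), indent=1,
                                    sort_keys=True))

    def transect_risk_df(self) -> pd.DataFrame:
        rows = []
        for state in ("current", "restored"):
            for epoch in EPOCHS:
                for t in self.w.transects:
                    rows.append({
                        "transect": t.id, "region": t.region_id,
                        "state": state, "year": epoch,
                        "protection_rp": self.protection[state][epoch][t.id],
                        "ead": self.ead[state][epoch][t.id],
                        "eaap": self.eaap_[state][epoch][t.id]})
        return pd.DataFrame(rows)

    def region_risk_df(self) -> pd.DataFrame:
        df = self.transect_risk_df()
        g = df.groupby(["region", "state", "year"], as_index=False)[
            ["ead", "eaap"]].sum()
        g["scenario"] = self.scenario.name
        return g


def run_pipeline(config: RunConfig | None = None) -> PipelineResult:
    """Execute every stage in order; any failure halts with the stage named."""
    config = config or RunConfig()
    st = _Stages(config)
    for stage in ("world", "attenuation", "design", "risk_current",
                  "risk_restored", "economics", "equity"):
        try:
            getattr(st, stage)()
        except Exception as exc:
            raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc
    st.write_outputs()
    return PipelineResult(
        world=st.w, attenuation=st.attenuation_df,
        protection=pd.DataFrame(
            [{"transect": tid, "state": state, "year": epoch,
              "protection_rp": rp}
             for state, by_e in st.protection.items()
             for epoch, per in by_e.items() for tid, rp in per.items()]),
        transect_risk=st.transect_risk_df(), region_risk=st.region_risk_df(),
        bca=st.bca_df, sensitivity=st.sens_df,
        excluded_regions=st.excluded_regions, equity_table=st.equity_df,
        wealth_hists=st.wealth_df, rank_tests=st.tests_df,
        manifest=st.manifest)
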