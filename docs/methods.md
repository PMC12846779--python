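# Methods

This note documents the models, parameter choices and numerical decisions
behind `hybridcoast`, and what the synthetic test worlds do and do not show
about real coastlines.

## Synthetic coastal worlds

All external data a hybrid-defense assessment consumes are emulated by
`synthetic_world.generate_world(config, seed)`, which is bit-reproducible in
`(config, seed)`:

- **Extreme sea levels** per transect follow `WL(T) = μ + β ln T` with
  `μ ~ U(1.0, 2.0) m` and `β ~ U(0.2, 0.45) m`. The Gumbel-type log-linear
  form matches peak-over-threshold practice for surge extremes and gives
  closed-form curves for analytic tests; it is a stand-in, not a claim about
  any reanalysis product.
- **Offshore waves**: `Hs(T) = Hs₁₀₀ (1 + 0.15 ln(T/100))`, floored at
  `0.2 Hs₁₀₀`, with `Hs₁₀₀ ~ U(1.5, 3.0) m`. Wave incidence is taken coast
  normal (worst case).
- **Terrain**: a 200 × 200 grid of 1 km cells; elevation rises inland at
  0.8 m/km from a low coastal strip (`U(0, 1.5) m`) with 0.3 m Gaussian
  noise, so the coast is low-lying on average but ridges and basins occur.
- **Exposure**: built-up fraction peaks at 0.45 near the coast and decays
  with an e-folding scale of 12 km, with lognormal scatter and 25 % empty
  cells; population follows built-up area at 4,000 persons per built-up
  km². Maximum damages per cell combine occupancy shares (75 % residential,
  15 % commercial, 10 % industrial), building densities (20 %/30 %/30 %) and
  a unit construction cost of 1,000 currency/m² scaled linearly with the
  region's GDP per capita against a 10,000 reference.
- **Mangroves**: 40 shore-normal transects of 4 km; 40 % carry an existing
  belt (`U(50, 500) m`), 60 % carry a raw restorable width
  (`U(50, 400) m`). Raw widths are averaged over a 1 km anchor-distance
  buffer restricted to transects in regions with simulated flood risk;
  transects without qualifying neighbours get zero.
- **Administrative structure**: four alongshore regions in two countries,
  each with an income group, urbanization level, subsidence rate
  (`U(0, 6) mm/y`) and an implementation cost drawn lognormally around the
  median 8,143 per ha, clipped to the published range 27–253,300.
- **Wealth and poverty**: the wealth index is `N(0, 1)` per cell plus a
  monotone trend of +0.01 per km inland (the default encodes a *negative*
  wealth–exposure correlation: coastal populations are poorer), centred to
  zero per country. Poverty likelihood is a logistic transform of wealth
  anchored at an income-group base rate, keeping the two indicators
  coherent.
- **Scenarios**: two RCP/SSP combinations with fixed epoch offsets
  (RCP4.5: 0/0.18/0.42 m at 2020/2050/2080 at the median; RCP8.5:
  0/0.22/0.60 m; 5th/95th percentiles bracket these) and country-level GDP
  (≈ 2 %/y and ≈ 3 %/y) and population (≈ 1 %/y and ≈ 1.5 %/y) growth
  rates. No gravitational-rotational fingerprints are modelled — offsets
  are spatially uniform per epoch.

What the generator does **not** emulate: convoluted mangrove shorelines
(transects are straight and shore-normal), tropical-cyclone wave physics,
spatially correlated exposure clusters (cities), sediment dynamics and
mangrove accretion, and realistic absolute magnitudes of exposed capital.
Passing tests therefore demonstrate correctness of the chain's mechanics
and directional conclusions, not calibrated dollar values: the toy world's
benefit–cost ratios come out an order of magnitude above typical
global-study values simply because its coastal exposure per transect is
dense relative to restoration costs.

## Wave attenuation

The integrator marches the significant wave height shoreward in Δx = 10 m
steps over the submerged profile, applying
`H ← H · exp(−c Δx / max(h, 0.1 m))` followed by the breaking cap
`H ≤ γ_br h`, with `γ_br = 0.78`, `c = c_v = 0.007` inside the vegetated
band and `c = c_b = 0.0002` over bare bed. The decay denominator uses the
segment-midpoint depth, which makes the scheme second order: halving Δx
changes smooth-profile results by well under 0.5 %. The vegetated band
occupies the innermost (landward) part of the submerged transect — a fringe
mangrove assumption — and a restored band abuts the existing band on its
seaward side. The constants give ≈ 50 % height reduction over 200 m of
mangrove in 2 m of water and are exposed in configuration.

The lookup table evaluates the same integrator on an idealised planar
foreshore: the bed starts at the axis depth below still water and rises at
the axis slope across the belt, levelling off at a minimum dike-toe depth
of 0.1 m (a dike toe is never at the exact waterline; without this floor
the table value would collapse through hundreds of e-foldings at the drying
limit and no table could interpolate it). Values are interpolated
multilinearly in `log H` on log-transformed slope/depth/Hs axes and linear
width — exact at nodes, exact for uncapped exponential decay, and measured
at ≤ ~4 % relative error against direct integration at the default axis
density (6 slopes × 14 depths × 16 Hs values × 11 widths). Queries outside
the axes clamp to the edge. The pipeline integrates transect profiles
directly (they are planar anyway); the table is the fast path for large
transect sets and is what the `attenuate` machinery serialises to NetCDF.

## Overtopping and protection levels

Mean overtopping discharge of the smooth, berm-less 1:3 dike uses the
canonical mean-value formulation with all influence factors 1:

    q_break = √(g Hm0³) · (0.023/√tanα) · ξ · exp(−(2.7 Rc/(ξ Hm0))^1.3)
    q_max   = √(g Hm0³) · 0.09 · exp(−(1.5 Rc/Hm0)^1.3)
    q       = min(q_break, q_max),   ξ = tanα / √(2π Hm0 / (g Tm²))

The mean period is derived from a fixed deep-water steepness of 0.04, since
the synthetic wave climate does not model periods. `required_freeboard`
inverts each branch in closed form and takes the smaller candidate (valid
because q is the pointwise minimum of two decreasing functions); round
trips hold to 10⁻⁶ relative.

Crests are designed at the regional protection standard — a default
income-group × urbanization table spanning 2 y (low-income rural) to
1,000 y (high-income urban), configuration-overridable — with *current*
mangroves: restoration is evaluated as a risk-reduction channel on existing
crests, not as a crest-lowering design saving. The effective protection
level of a fixed crest at any year is the largest return period, searched
on 60 log-spaced points in [2, 1,000] y with interpolation in ln T, whose
water level plus required freeboard (after attenuation under the given
mangrove state, with the scenario's sea-level offset) still fits under the
crest; if even T = 2 fails the transect is flagged substandard.

## Inundation and risk

Planar ("bathtub") flooding runs a best-first (priority-queue) flood fill
from coastal seed cells over 8-connected neighbours: a cell at along-path
distance d km floods iff `dem < WL − λ d` (diagonals count √2), and water
propagates only through flooded cells, so disconnected basins stay dry.
λ defaults to 0.5 m/km. Every flooded cell records the transect catchment
through which the water arrived (coastal cells are assigned to transects by
nearest anchor).

Expected annual damage integrates the impact–probability curve with the
trapezoidal rule. The curve is truncated at the protection probability
`p_prot = 1/T_prot`: impacts at more frequent events are zeroed and the
impact exactly at `p_prot` is interpolated linearly **in p** (not in T —
this choice changes truncation values and is therefore fixed and
documented). The unsimulated tail beyond the 1,000-y event contributes a
constant-impact rectangle `I(p_min)·p_min` by default; a flag drops it.
EAAP uses the identical routine with exposed population as the impact.

In the pipeline, depth grids are computed undefended and truncation is
applied once, inside the integration, per transect catchment. Because
restoration only raises protection levels (the surge water level and hence
the depth grids are state-independent), avoided damages are guaranteed
nonnegative by the monotonicity of truncation.

Risk is evaluated at three epochs (2020, 2050, 2080) and interpolated
piecewise-linearly to annual series, extrapolating 2080→2100 with the
2050–2080 slope floored at zero. Three epochs keep a full run at seconds
on one CPU while preserving the annual-cashflow structure.

## Restoration economics

Benefits per year are `B_t = s · (1 − e^{−k(t−t₀)}) · B_pot(t)` with
survival `s = 0.75` (sensitivity 0.50/0.90) and `k = ln(100)/10 ≈ 0.4605`
so regrowth reaches 99 % ten years after planting — the concrete reading of
"saturation at 10 y", exposed in configuration. Costs book implementation
(`IC` per ha × area) plus opportunity costs (`1.4 × IC`) as a year-0 lump
sum — the total-cost reading `TC = IC + 1.4·IC`, with an annuitised
alternative behind a flag — and 1 %/y maintenance scaled by country GDP
growth and by survival (only the surviving stand is maintained; mortality
does not refund the implementation outlay, and no replanting is assumed).
Discounting runs from the restoration year 2020 to 2100 at r = 5 %
(sensitivity 3/8/10 %); `sign(NPV) = sign(BCR − 1)` holds exactly and is
asserted across the full 4 × 3 × 2 sensitivity grid. Regions with less
than 5 ha of restorable area are dropped and logged; retained regions sum
transect areas (restorable width × alongshore spacing) and benefit series.

## Equity analysis

Flood-prone is operationalised as the undefended 1,000-y inundation extent
(the most inclusive simulated event; configurable down to e.g. 100 y). The
benefit group comprises flood-prone cells in catchments of transects with
positive restorable width and positive avoided damages at any epoch. The
poverty table reports expected poor (`Σ pop·p_poverty`) per group now and
in 2050, scaling population by scenario growth with poverty likelihood held
fixed. Wealth distributions are population-weighted histograms normalised
to unit area. Rank tests draw population-weighted wealth samples (values
repeated by rounded counts, subsampled to a 20,000 budget) and apply a
Mann–Whitney U test: midranks for ties, tie-corrected variance
`n₁n₂/12·((N+1) − Σ(t³−t)/(N(N−1)))`, 0.5 continuity correction on the
normal deviate, and exact enumeration of all labelings when `n₁+n₂ ≤ 12`.
Whether flood-prone populations should use defended or undefended extents
is not settled; both modes run, undefended being the default.

## Numerical and degenerate-input conventions

- Hazard curves interpolate in ln T and must be nondecreasing; violations
  raise.
- A transect dry at the evaluation water level attenuates to zero wave
  height (logged), and its crest design degenerates to the surge level.
- Unsorted risk-curve points are sorted with a warning; negative
  restoration benefits are flagged, never clipped.
- Lookup queries outside axis bounds clamp to the edge (logged); a
  single-node axis behaves as nearest-node.
- The flood fill treats equal heads to 10⁻¹² tolerance; catchment ties go
  to the first-settled path.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; reruns are bit-identical, including fixture
  checksums.

## Known limitations

Beyond the generator's idealisations listed above: no phase-resolving or
spectral wave modelling; no berms, oblique waves or probabilistic
overtopping variants; no dike breaching (overtopping exceedance equals
flooding); no compound river/rainfall flooding; no co-benefits (carbon,
fisheries, timber) in the economics; no marginal-utility weighting in the
equity analysis; subsidence is prescribed, not modelled.
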