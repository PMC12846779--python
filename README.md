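# hybridcoast

Flood-risk reduction, benefit–cost and distributional-equity analysis of
**mangrove restoration in hybrid coastal defenses** — a vegetated foreshore
in front of an engineered dike.

Mangrove belts dissipate wave energy before it reaches a dike, so restoring
lost mangrove width in front of existing dikes raises the effective
protection standard of the defense without touching the crest. `hybridcoast`
implements the full assessment chain for this intervention and exercises it
end-to-end on seeded synthetic coastal worlds that emulate the statistical
structure of the global datasets such studies consume (extreme sea levels,
offshore waves, a coastal DEM, built-up/population/GDP grids, mangrove
extents, protection standards, wealth and poverty grids, RCP/SSP scenarios).
It is intended for researchers who want a transparent, fully testable
implementation of each link in the chain.

## The model chain

1. **Hazard.** Per shore-normal transect, extreme still-water levels follow
   a Gumbel-type curve `WL(T) = μ + β ln T` at nine return periods
   (2–1,000 y); offshore significant wave height `Hs(T)` grows
   logarithmically, anchored at the 100-y value.
2. **Wave attenuation.** Waves march shoreward with depth-limited breaking
   (`H ≤ γ_br h`, `γ_br = 0.78`) and exponential decay
   `H ← H·exp(−c Δx / h)` with `c = 0.007` inside the mangrove belt and
   `0.0002` over bare bed. A 4-D lookup table
   (slope × depth × Hs × belt width) reproduces the integrator to ≈ 5 %.
3. **Dike design.** Overtopping of a smooth 1:3 dike uses the mean-value
   empirical formulas, `q = min(q_break, q_max)` with
   `q_max = √(g·Hm0³)·0.09·exp(−(1.5 Rc/Hm0)^1.3)`; crests are designed so
   overtopping stays below 1 l/s/m at the local protection standard (2–1,000
   y by income group and urbanization). Sea-level rise and subsidence
   degrade, and restoration raises, the effective standard of a fixed crest.
4. **Inundation & risk.** A planar flood fill with hydraulic connectivity
   and an inland resistance factor converts water levels to depth grids.
   Event impact per cell is `I(w) = θ_r(w)M_r + θ_c(w)M_c + θ_i(w)M_i`
   (damage fractions saturate at 6 m depth); expected annual damage is the
   trapezoidal integral of impact over annual exceedance probability,
   truncated at the protection standard, `D = ∫ I(p) dp`. Replacing damage
   with exposed population gives the expected annual affected population.
5. **Benefit–cost.** Avoided damages `B = D_without − D_with`, scaled by a
   regrowth factor `1 − e^{−k(t−t₀)}` (99 % at 10 y) and a survival rate
   (50/75/90 %), run against implementation costs (median 8,143 per ha),
   opportunity costs (1.4 × implementation) and 1 %/y maintenance to 2100.
   `BCR = Σ B_t/(1+r)^t ÷ Σ C_t/(1+r)^t`, `NPV = Σ (B_t − C_t)/(1+r)^t`,
   with discount-rate sensitivity at 3/5/8/10 %. Regions with under 5 ha of
   restorable mangrove are excluded.
6. **Equity.** Population splits into groups outside flood-prone areas,
   inside them, and inside with restoration benefits; the groups are
   overlaid with poverty likelihood and the wealth index (0 = country mean)
   and compared with a tie-corrected Mann–Whitney U test (exact enumeration
   for small samples).

## Worked example

```sh
hybridcoast report --seed 7 --outdir out/
```

prints (and writes to `out/report.txt`):

```
hybridcoast run summary
scenario: RCP45_SSP2  percentile: 50  seed: 7
EAD 2020 current:  287,909,785
EAD 2020 restored: 190,972,829  (avoided 96,936,956)
EAAP 2020 current:  19,553
EAAP 2020 restored: 11,893
regions in BCA: 4  excluded (<5 ha): 0
median BCR: 43.69  total NPV: 4,469,751,733
```

Reading: on this 200×200-cell synthetic coast with 40 transects, full
restoration of the restorable mangrove belts avoids ~97 M (34 %) of the
expected annual damage and ~7,700 of the expected annually affected people
under present-day conditions, and every subnational region passes the
benefit–cost test at a 5 % discount rate and 75 % survival. Magnitudes are
properties of the synthetic world, not of any real coastline; directions
and identities are what the test suite pins down.

The same run is available piecewise (`hybridcoast simulate-world`,
`attenuate`, `design`, `inundate`, `risk`, `bca`, `equity`) and from Python:

```python
from hybridcoast import RunConfig, run_pipeline
result = run_pipeline(RunConfig(seed=7))
print(result.region_risk)      # EAD/EAAP per region, state, epoch
print(result.bca)              # discounted benefits, costs, BCR, NPV
print(result.rank_tests)       # wealth-distribution comparisons
```

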