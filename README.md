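# fishclim

Climate-driven shifts in thermally available habitat are redistributing the
species that US commercial fisheries land. `fishclim` is a tested pipeline
for the economic side of that problem: given projected habitat changes for
16 major US fisheries under two emissions scenarios (RCP 4.5 and RCP 8.5),
it screens the implied landings changes in present-value terms, estimates a
two-stage inverse demand system from monthly dockside data, forecasts
expenditures and ex-vessel prices through 2100, and measures the consumer
welfare impacts with a distance-function approach. It is aimed at fisheries
and environmental economists who want a reproducible, fully synthetic-data-
testable implementation of this class of analysis.

## The model

**Screening.** For each species-region, baseline landings are the 2007–2016
annual means (revenues CPI-deflated to 2018 US$). Per-GCM habitat totals in
five 20-year bins give fractional changes vs the baseline bin,
Δh = (H(bin) − H(B0))/H(B0), ensembled as the arithmetic mean over five
GCMs, anchored at bin midpoints and linearly interpolated to annual
multipliers m_t. Landings are projected proportionally
(landings_t = baseline × m_t) and discounted at a 3% real rate over
2021–2100; the 80-year annuity factor is Σ_{k=1..80} 1.03^−k = 30.2008.
Monte Carlo intervals bootstrap the ten baseline years and draw one GCM
uniformly per replicate.

**Demand.** Ex-vessel prices respond to exogenous landings through an
inverse almost ideal demand system (IAIDS): expenditure shares

  wᵢ = αᵢ + Σⱼ γᵢⱼ ln qⱼ + βᵢ ln Q,  ln Q = Σⱼ wⱼ ln qⱼ (Stone index),

estimated as a seemingly unrelated regression by iterated feasible GLS with
the adding-up (Σαᵢ = 1, Σβᵢ = 0, Σᵢγᵢⱼ = 0), homogeneity (Σⱼγᵢⱼ = 0) and
symmetry (γᵢⱼ = γⱼᵢ) restrictions imposed exactly — 12 free parameters for
a four-good system. Demand is two-stage: one system allocates total seafood
expenditures among four fishery groups, and four within-group systems
allocate each group's budget among its member species. Quantity
flexibilities at mean shares are fᵢⱼ = −δᵢⱼ + (γᵢⱼ + βᵢ w̄ⱼ)/w̄ᵢ; the
published-style "price elasticity" tables report the entries of F⁻¹ with
delta-method inner-95th-percentile bounds.

**Forecast and welfare.** Total expenditures grow with GDP through an
income elasticity of 0.11, E_t = E₂₀₂₀ (GDP_t/GDP₂₀₂₀)^0.11. The estimated
systems simulate the two-stage budget allocation each year; implied prices
are species expenditures over harvests. Welfare uses the translog distance
function dual to the IAIDS, ln D(q, u) = a(q) − u·b(q), benchmarked at
baseline harvests (D(q₀, u₀) = 1, so u₀ = a(q₀)/b(q₀)); annual impacts are
monetized as W_t = E_t (1 − 1/D(q_t, u₀)) per fishery group and discounted
to NPVs at 3%.

All external inputs (the NMFS monthly panel, GCM habitat grids) are
emulated by a seeded synthetic generator drawn from a *known* two-stage
IAIDS process, so every stage is testable — including exact parameter
recovery on noise-free panels.

## Worked example

```python
import numpy as np
from fishclim import InverseAIDS, SyntheticConfig, gen_demand_history, flexibilities
from fishclim.pipeline import panel_to_stage_obs

cfg = SyntheticConfig(seed=42)                  # 120 months, 16 species
panel = gen_demand_history(cfg)                 # monthly landings + revenue
stage1, stage2 = panel_to_stage_obs(panel, cfg.species_groups)
model = InverseAIDS().fit(stage1["lnq"], stage1["w"], labels=stage1["labels"])
tab = flexibilities(model.params_, model.mean_shares_)
for name, e, lo, hi in zip(stage1["labels"], np.diag(tab.elasticity),
                           tab.own_elas_lo, tab.own_elas_hi):
    print(f"{name:16s} {e:7.3f}  [{lo:7.3f}, {hi:7.3f}]")
```

prints the first-stage own-price elasticities with their delta-method
bounds:

```
Lobster/crab      -0.756  [ -0.772,  -0.739]
Shrimp/mollusk    -0.765  [ -0.782,  -0.748]
High-value fish   -0.680  [ -0.728,  -0.633]
Low-value fish    -0.705  [ -0.755,  -0.654]
```

All four own-price elasticities are negative (downward-sloping demand) and
precisely estimated, as expected from the diagonal-dominant substitution
structure of the generating process.

The full pipeline runs from the shell:

```sh
fishclim all --seed 1 --outdir out/
```

writing the screening tables (per-species and regional PV changes, Monte
Carlo harvest projections), elasticity tables, the expenditure and price
forecasts, annual welfare series, NPVs, and a JSON manifest from which
every output is reproducible byte-for-byte.

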