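# Methods

This note documents the models, numerical choices and limitations of
`fishclim`. It is written for a reader who wants to know exactly what the
package computes and what its passing tests do and do not establish.

## Screening model

The screening stage asks a deliberately simple question: if landings of
each species moved in direct proportion to its thermally available
habitat, what would the present value of ex-vessel revenues look like over
2021–2100 relative to holding landings at the 2007–2016 baseline?

* **Baseline statistics.** Monthly records are summed to annual totals per
  (species, region); the baseline is the mean over years and the sample SD
  (n−1 denominator) is retained together with the per-year values for
  bootstrap resampling. Revenues are CPI-deflated to 2018 US$ before
  collapsing. With fewer than two years the SD is reported missing.
* **Record matching.** Landings records are classified exactly once, in
  order: automated name match against the habitat table, manual match via
  a synonym map, multi-species exclusion, then a de minimis exclusion for
  still-unmatched records with mean revenue strictly below $100,000/yr
  (0.1 MM$). Applying the de minimis test only to otherwise-unmatched
  records mirrors the published record-processing order. A species
  appearing in both the synonym map and the multi-species set is an error:
  the curation is ambiguous.
* **Habitat changes.** Habitat totals come in five bins (B0: 2007–2020,
  T1–T4: four 20-year windows to 2100). Per GCM,
  Δh(bin) = (H(bin) − H(B0))/H(B0); the five-GCM ensemble is the
  arithmetic mean of the per-GCM fractional changes (mean of ratios). The
  alternative — percent change of mean habitat — differs only at second
  order in the GCM spread; the mean-of-ratios reading applies the ensemble
  averaging after the percent-change step. A zero baseline bin raises an
  error: the percent change is undefined, and such degenerate records
  (the snow-crab case, whose modeled habitat vanishes under high
  emissions) are excluded upstream.
* **Annualization.** The source tables define only 20-year bins. Bin
  values are anchored at bin midpoints (2013.5, 2030.5, 2050.5, 2070.5,
  2090.5), linearly interpolated between anchors, and held flat from
  2090.5 to 2100. This choice is smooth, reproducible, and respects the
  bin means at their midpoints; whether the original annual trajectories
  interpolated bins or repeated them stepwise is not documented, so the
  interpolation convention is flagged in output metadata (the manifest).
* **Discounting.** PV discounts to end-2020: the first discounted year is
  2021 with exponent 1, so a constant unit series over 2021–2100 has
  PV = Σ_{k=1..80} 1.03^−k = 30.2008. This convention reproduces the
  published percentage columns (e.g. white shrimp +9%, Dungeness crab
  −14.2%) exactly, which is how it was fixed.
* **Monte Carlo intervals.** Each replicate bootstraps the ten baseline
  annual values (sampling years with replacement) and draws one GCM
  uniformly; the percent change is (mean_draw × m − mean_full)/mean_full
  and the CI is the 2.5th/97.5th percentile band. The published analysis
  names these two variance sources but not the sampling scheme; this is
  the simplest scheme using exactly those two sources, with landings and
  habitat drawn independently (joint resampling is not identifiable from
  the description). The point estimate is the ensemble-mean percent
  change, to which the simulation converges as interannual variance
  vanishes.

## Demand system

The inverse almost ideal demand system (IAIDS) treats quantities as
exogenous (harvests are set by management, not by price) and lets prices
adjust through expenditure shares:

    w_i = alpha_i + sum_j gamma_ij ln q_j + beta_i ln Q.

* **Quantity index.** The estimable form uses the Stone index
  ln Q = Σ w_j ln q_j (LA-IAIDS). The full translog index is retained in
  the welfare stage, where the alpha0/beta0 normalizations matter. The
  estimator iterates the index: the first pass uses observed shares, then
  the index is rebuilt from fitted fixed-point shares and the system
  re-estimated until the parameters stabilize. The observed-share index
  carries the same measurement noise as the dependent shares, which
  biases beta; the fitted index is a function of quantities only and
  removes that simultaneity. On noise-free data the first pass already
  fits exactly and the iteration is a no-op, preserving exact recovery.
* **Restrictions.** Adding-up, homogeneity and symmetry are substituted
  into the design matrix, so they hold exactly by construction:
  homogeneity turns the regressors into relative log quantities
  (ln q_j − ln q_n), symmetry ties gamma across equations, and the n-th
  equation is dropped (adding-up makes the system covariance singular)
  with its parameters recovered afterwards. For four goods this leaves
  (n−1) + (n−1) + n(n−1)/2 = 12 free parameters. Estimates are
  equivariant to which equation is dropped (verified to 1e−6 on
  noise-free data).
* **Estimation.** Iterated feasible GLS to a 1e−8 relative parameter
  tolerance (at most 100 iterations), the maximum-likelihood fixed point
  of the SUR problem; one-step FGLS would depend on equation order. The
  residual covariance is checked for singularity (condition > 1e12
  raises, advising more data); an exactly-fitting system (noise-free
  synthetic data) is detected by residuals below 1e−9 and returned from
  the OLS step with a zero parameter covariance. The estimation requires
  at least three observations per free parameter and full-rank
  regressors.
* **alpha0 and beta0** are not identified by the share equations; they
  are fixed at 0 and 1 and act as welfare-stage normalizations.
* **Flexibilities and elasticities.** Uncompensated flexibilities at mean
  shares are f_ij = −δ_ij + (γ_ij + β_i w̄_j)/w̄_i — the sign of the beta
  term follows from differentiating the share equations with the index
  gradient ∂lnQ/∂lnq_j = w̄_j, and is verified against a central finite
  difference of the implied inverse demand (p_i = w_i E/q_i) to 1e−4. An
  inverse demand system natively yields flexibilities; since the
  published tables are labeled price elasticities, both readings are
  computed and the inverse-matrix elasticities (entries of F⁻¹) populate
  the reported elasticity table, with the chosen reading flagged in the output.
  Interval bounds come from the delta method: the statistic's gradient in
  free-parameter space is taken by central differences (relative step
  1e−6) and the interval is point ± 1.96·se.

## Forecasting

* **Expenditures.** E_t = E_anchor (GDP_t/GDP_anchor)^0.11 anchored at
  (2020, E_2020). The packaged GDP path is decadal and interpolated
  linearly to annual values. Anchoring at 2020 (rather than compounding
  from the 2007–2016 average) uniquely reproduces every published
  expenditure row; growth relative to the 2007–2016 average (16.5% by
  2100) is reported separately. In synthetic runs the anchor is the
  panel's own baseline annual expenditure.
* **Budget allocation.** The stage-1 group quantity index is a Stone
  index over member species with *frozen* base-period within-group
  shares, avoiding simultaneity between the forecast shares and the
  index. Forecast shares are evaluated as deviations from the estimation
  sample means (the GLS normal equations zero each equation's mean
  residual, so prediction at the sample-mean quantities returns the mean
  shares exactly); this gives an exact calibration identity — baseline
  quantities with baseline expenditure reproduce baseline revenues. By
  adding-up, predicted shares sum to one and the allocation conserves the
  budget at both stages to machine precision. A non-positive predicted
  share aborts with the year and good named: the linear share equations
  have been extrapolated outside their region of validity.
* **Prices.** p_t = E_t/q_t per species (MM$ over MM lb = $/lb). The
  baseline-price window defaults to the estimation window (2007–2016
  in the emulated data); the published baseline prices use a longer
  1996–2016 window that monthly estimation data cannot reproduce.

## Welfare

The distance function dual to the IAIDS is translog:
ln D(q, u) = a(q) − u b(q) with
a(q) = α0 + Σα_i ln q_i + ½ΣΣγ_ij ln q_i ln q_j and
b(q) = β0 Π q_i^{−β_i} (the exponent sign flip relative to the estimated
share-equation betas makes ∂lnD/∂lnq_i reproduce the estimated shares at
D = 1; with it, utility enters negatively and the restriction set
delivers exact linear homogeneity D(λq, u) = λD(q, u), verified by a
λ-scaling test). Utility is benchmarked at baseline harvests:
u0 = a(q0)/b(q0).

* **Monetization.** W_t = E_t (1 − 1/D(q_t, u0)). The exact published
  monetization is not recoverable from the main text (it is deferred to
  unavailable supplementary material); this money-metric form is exact
  for proportional bundle changes (W = E(1 − 1/λ) when q = λq0), has the
  correct sign and zero point, and is bounded above by E_t. It is the
  single largest documented modeling gap; an equivalent-variation-style
  variant W_t = E_t (D − 1) is exposed behind the ``monetization``
  config switch.
* **Grouping.** Each fishery group's welfare uses its own second-stage
  distance function and its forecast stage-1 expenditure; cross-group
  interactions enter only through the expenditure allocation, matching
  the per-group presentation of the published NPVs. The total is the sum
  over groups by construction.
* **Discounting.** NPVs discount to end-2020 at 3%; the 2020 row of the
  annual table is reported (its welfare is forced by near-baseline
  quantities) but carries no weight in the NPV.
* **Baseline bundle.** The welfare benchmark and forecast quantity paths
  use the geometric mean of the monthly quantities (the estimation anchor
  point), so the zero-change invariant — flat habitat and zero income
  elasticity imply identically zero welfare — holds exactly.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes; it
defines the study conditions and is not tuned per test.

* **Quantities.** Log quantity per species = species mean (set by the
  published baseline harvests, MM lb/month) + a 12-month sinusoid
  (amplitude 0.3, random phase) + AR(1) noise (ρ = 0.5, sd 0.15).
  Quantities are generated in logs, so they are positive by construction.
* **Shares.** Within each month, stage-2 shares per group are the exact
  closed-form fixed point of the Stone-index share equations
  (lnQ = (α + Γlnq)′lnq / (1 − β′lnq)); group indices then feed the
  stage-1 fixed point. Mean-zero Gaussian noise (sd 0.01) is added to the
  first n−1 shares with the last share the residual, respecting adding-up
  by construction. Revenue = share × stage expenditure; total expenditure
  is 3,080 MM$/yr spread evenly over months.
* **True parameters.** Alphas are recentred so the fixed point at the
  baseline log quantities reproduces the published baseline revenue
  shares; gamma = k(ww′ − diag(w)) (symmetric, zero row/column sums,
  negative diagonal) with k between 0.45 and 0.65 across systems, and
  small betas (±0.04 scale). This yields all-negative own-price
  elasticities of seafood-like magnitude.
* **Habitat.** Future-bin totals are baseline × (1 + trend(bin)) ×
  exp(ε), ε ~ N(0, 0.08) independent across GCMs and bins (log-normal for
  positivity); the baseline bin is noise-free and shared across GCMs. The
  default trends are anchored to the published ensemble harvest changes
  (2050 → bin T2, 2090 → bin T4, T1 = T2/2, T3 midway), so synthetic runs
  reproduce the published qualitative pattern (e.g. lobster/crab welfare
  negative and shrimp/mollusk positive under high emissions).

What the generator does **not** emulate: real species-specific
seasonality, cross-species quantity correlations, regional disaggregation
of multi-region fisheries (each species is assigned one region), GCM
spatial fields, or price measurement error. Passing tests therefore show
the estimator and pipeline are correct for data satisfying the model's
assumptions — not that the published elasticity or welfare *levels* are
recovered, which would require the undeposited NMFS and GCM inputs.

## Problem sizes and determinism

Default runs use 120 months × 16 species, 10,000 Monte Carlo draws, and
five GCMs × two RCPs × five bins of habitat data; a full end-to-end run
takes a few seconds on one CPU. All randomness flows from a single seed
through stage-partitioned `numpy` SeedSequence substreams (panel,
habitat, screening Monte Carlo), so adding draws to one stage does not
perturb another and every output file is reproducible byte-for-byte from
the manifest.

## Known limitations

* Harvests are exogenous: no producer surplus, fleet dynamics or
  management response; imports and aquaculture substitution are outside
  the demand system.
* The LA-IAIDS Stone approximation, the monetization form, and the
  bin-interpolation convention are documented choices where the source
  analysis is underdetermined; each is flagged where it surfaces.
* The delta-method intervals assume approximate normality of the
  estimator; with 120 monthly observations and 12 free parameters this is
  adequate on the synthetic process but untested on real data.
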