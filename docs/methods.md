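# Methods

## The statistical model

The package treats an urban quantity *Y* (CO₂ emission, PM2.5 emission, or
PM2.5 concentration) conditional on city population *P*.  Three nested
levels of description are implemented:

1. **Mean scaling law** ⟨*Y*|*P*⟩ = A·*P*^β.  Sub-linear β (< 1) means lower
   per-capita values in larger cities.
2. **Scaling form of the conditional distribution**
   ρ(*Y*|*P*) = *P*^(−β) F(*Y*·*P*^(−β)).  A generic two-exponent form
   ρ = *P*^(−a) f(*Y*·*P*^(−b)) must have a = b: substituting
   z = *Y*·*P*^(−b) in ∫ρ d*Y* = 1 leaves a factor *P*^(b−a) that can equal 1
   for all *P* only when the exponents coincide.  The collapse machinery
   makes this argument executable — every rescaled density must still
   integrate to 1, and curves from all population bins superimpose when the
   scaling holds.
3. **Spatial heterogeneity** via multifractal box counting of the measure on
   a grid, which captures how strongly the local scaling of mass varies from
   place to place.

## Synthetic generators and their defaults

The generators define the study conditions for every test and for the
acceptance computations; real inventories are not required.

* **Populations**: discrete Zipf-like tail, density exponent 2.0 (CCDF
  exponent 1), minimum 1,000 inhabitants, 50,000 cities.  Sampling is
  inverse-CDF on a continuous Pareto of shape `zipf_exponent − 1` rounded up
  to an integer — simple, exactly reproducible, and the tail exponent is
  directly checkable by a Hill estimate.  Broad population distributions of
  this kind are the conventional stand-in for European settlement-size data;
  the downstream estimators do not depend on the specific broad law chosen.
* **Emissions**: `Y = A·P^β·10^ε`, ε ~ N(0, σ) with σ = 0.5 decades, matching
  multi-decade scatter at fixed population.  Defaults β = 0.81 (CO₂-like)
  and γ = 0.72 (PM2.5-emission-like).  With σ = 0 the law is exact and the
  estimators must recover β to machine precision.
* **Concentration**: median `c·P^δ` below a population knee of 10,000 and
  constant above it (continuous at the knee — the empirical flattening is
  smooth, so the knee carries a single multiplicative constant), δ = 0.08,
  scatter 0.2 decades, prefactor 7.2 so the plateau sits near 15 µg/m³, a
  realistic ambient PM2.5 level.
* **Cascade grids**: multiplicative 2×2 cascade, depth 8 (256×256), weights
  (0.4, 0.3, 0.2, 0.1).  The deterministic cascade is the analytic oracle:
  its partition function at box side 2^k is exactly (Σᵢwᵢ^q)^(depth−k), so
  τ(q) = −log₂ Σᵢwᵢ^q.  The randomized variant permutes the four weights
  independently per subdivision (same τ(q) in expectation) and is off by
  default so the closed form stays exact.
* **Seeding**: one seed per run; each operation draws from a named
  `default_rng([seed, crc32(stream_name)])` stream, so adding an operation
  never shifts the draws of existing ones.

What the generators deliberately do **not** emulate: the true spatial layout
of cities, country-level heterogeneity of exponents, spatial correlation
between neighbouring cities' emissions, and measurement error in population.
Passing tests therefore demonstrate correctness of the estimators under the
assumed generative structure, not that real inventories obey it.

## Estimators and numerical choices

* **Binned conditional mean**: bins linearly spaced in log₁₀P, default 6 per
  decade of populated range; arithmetic mean of the linear measure per bin;
  bins with fewer than `min_count = 10` cities are masked.  Zero or missing
  measures are dropped before the log transforms, with a logged count.
* **Conditional-mean exponent**: ordinary least squares of log₁₀(mean) on
  log₁₀P.  The "linear part" of the curve is selected automatically when no
  range is given: among contiguous windows of unmasked bins spanning at
  least 60 % of the populated decade range, the window with the highest r²
  wins; the selected window is always reported, making every fit auditable.
  Sparse high-population bins make the unweighted estimator noisier than its
  nominal OLS standard error suggests (adaptive window selection adds
  variability the residual-based stderr does not see); at the default study
  conditions (n = 50,000, σ = 0.5 decades) the realized seed-to-seed spread
  of the recovered exponent is about ±0.02.
* **All-data exponent**: OLS of log₁₀Y on log₁₀P over every city.  Agrees
  with the binned estimator for homoscedastic log-domain scatter and uniform
  log-density of P, and can legitimately differ otherwise — both are
  reported.
* **Conditional densities**: histograms on log-spaced measure bins per
  population bin, computed in log space (so boundary values are never
  dropped) and normalized in the *linear* measure variable, ∫ρ dY = 1
  within 1e−6.
* **Collapse quality**: each rescaled curve is interpolated in
  (log₁₀z, log₁₀ρ) onto a common 60-point grid restricted to its own
  occupied support; grid points where ≥ 2 curves are defined contribute the
  across-curve variance of log-density, and the score is the mean
  contribution.  It is 0 iff the curves coincide on shared support, and on
  cascade-generated data its minimum over an exponent scan sits at the
  generating exponent within grid resolution.

## Multifractal conventions

* Box sizes are powers of 2 of the base cell up to a quarter of the grid
  side; non-dyadic grids are zero-padded to the next box multiple (padding
  cells are empty and empty boxes are excluded, so padding is harmless).
  Dyadic sizes make the cascade and uniform-measure oracles exact.
* The measure is normalized to unit mass before Eq.-style moments; the
  factor is recorded.  Consequently Z₁(b) = 1 and τ(1) = 0 identically.
* Empty boxes are excluded at every q, so q = 0 counts occupied boxes
  (convention 0^0 := excluded).  Negative q are not offered: near-empty
  boxes make them numerically explosive and the analysis does not need
  them.
* q grid: 26 points uniform on [0, 5] (Δq = 0.2).  D₁ uses the
  information-dimension limit (slope of Σμ_b ln μ_b vs ln b) rather than the
  0/0 ratio.
* f(α) by central differences on the uniform q grid (one-sided at the
  ends); a non-uniform grid is rejected rather than silently differenced.
* The grid origin is fixed at the data bounding-box corner; no origin
  averaging is performed.  Origin sensitivity of box counting is a known
  limitation of the method and is accepted for determinism.

## Areal aggregation

Grid-to-polygon aggregation uses exact polygon–rectangle clipping (shapely)
rather than raster resampling.  Extensive quantities (emissions) split each
cell's mass proportionally to overlapped cell fraction — polygons that tile
the grid conserve total mass to 1e−9 relative.  Intensive quantities
(concentrations) take the area-weighted mean, so a constant field aggregates
to that constant for any polygon.  Emissions-extensive /
concentration-intensive is the physically sensible default and both are
available via a flag.  Coordinates are abstract planar; no reprojection or
dasymetric refinement is attempted.

## Impact calculus

* **Rescaled correlations**: cities with P ≥ 700,000 (default); emissions
  divided by P^β and P^γ from the conditional-mean fits (the conditional-mean
  exponents, not the all-data ones, are the natural choice since rescaling
  targets the conditional law); concentration is not rescaled because its
  conditional mean is flat in population above the knee.  Pearson r with the
  two-sided p-value from the t transform with n − 2 degrees of freedom.
* **PAF**: the exposure–response relation is a tabulated monotone curve
  (concentration → attributable fraction); interpolation is piecewise linear
  between knots and clamped to the end values outside the tabulated range
  (with a warning) — a bounded fraction must never be extrapolated.  The
  concentration is treated as the long-term exposure; where ambient levels
  have been falling, a single-year concentration makes the resulting PAF a
  lower bound.  This caveat is an assumption of the calculation, not
  modelled dynamically.
* **CO₂ balance**: per-region balance = emitted − captured, exact
  arithmetic; the aggregate offset fraction is Σcaptured/Σemitted, never the
  mean of regional ratios.  The capture model is through-origin least
  squares of capture on forest area (uncentered r²), and the forest
  scenario scales each region's capture linearly with its forest area
  (capped at the region's land area) at the region's own rate — an explicit
  proportionality assumption.

## Problem sizes

Test and acceptance computations use 50,000-city ensembles, 256×256 grids
(cascade depth 8) and 26-point q grids; each stage completes in seconds and
the statistical tolerances quoted above were chosen for these sizes.

## Known limitations

* Box counting is origin- and grid-orientation-sensitive; only one origin is
  used.
* The automatic fit-window selection is deterministic and auditable but not
  variance-optimal; exponents move at the ±0.02 level with bin count and
  min-count settings, which are therefore exposed as configuration.
* No maximum-likelihood tail estimation is offered — the two least-squares
  estimators are the object of study, not the best possible tail estimator.
* The exposure–response curve is an input; no relative-risk integration over
  exposure distributions is performed.
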