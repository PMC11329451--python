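# urbanscale

Tools for studying how urban emissions and air pollution scale with city
population, and for the downstream impact arithmetic that such scaling feeds:
health burden attributable to PM2.5 and the CO₂ offset provided by forests.

The package is aimed at quantitative geographers, environmental
epidemiologists and statistical physicists who work with city-level emission
inventories (CO₂ and PM2.5 in tons/yr), gridded concentration fields
(µg/m³) and regional forest/capture tables, and who want the estimators
behind "urban scaling law" claims as reusable, tested code rather than
one-off notebook cells.

## What it computes

**Scaling laws and data collapse.** For an urban quantity *Y* (emission or
concentration) and population *P*, the mean scaling law is *Y* ∝ *P*^β.  Two
least-squares estimators are provided: the *conditional-mean* exponent
(fit of log₁₀⟨*Y*|*P*⟩ on log₁₀*P* over log-spaced population bins,
restricted to the linear part of the curve) and the *all-data* exponent β₀
(fit over every city).  Beyond the mean, the conditional distribution is
assumed to obey a scaling form

ρ(*Y*|*P*) = *P*^(−β) F(*Y* · *P*^(−β)),

where normalization of ρ forces the same β in prefactor and argument.
`scaling.rescale_collapse` applies the transformation and
`scaling.collapse_quality` scores how well curves from different population
bins superimpose (0 = perfect collapse).

**Multifractal box counting.** A gridded measure μ is aggregated into boxes
of side *b* and the partition function Z_q(b) = Σᵢ μ_b(i)^q is fitted as
Z_q(b) ∼ b^τ(q) for moments q ∈ [0, 5].  Nonlinear τ(q) diagnoses
multifractality; a simple measure on a filled 2-D support has
τ(q) = 2(q−1), i.e. constant Rényi dimension D_q = τ(q)/(q−1) = 2.  The
singularity spectrum f(α) = qα − τ(q), α = dτ/dq, is computed by finite
differences.

**Impact calculus.** Population-rescaled emission correlations for large
cities (Ẽ_c = E_CO₂/P^β, Ẽ_p = E_PM2.5/P^γ, Pearson r with two-sided
p-values), the population attributable fraction (PAF) read from a monotone
exposure–response curve per region, and the regional CO₂ balance
(emitted − captured, with a what-if forest-cover scenario).

**Synthetic data.** `urbanscale.synthetic` generates city ensembles (Zipf
populations, conditional power-law emissions with lognormal scatter, a
concentration knee) and multiplicative-cascade grid measures whose τ(q) has
the closed form −log₂(Σᵢ wᵢ^q) — analytic oracles that make every stage of
the pipeline testable without external data. `urbanscale.geodata` reads and
writes city/region tables (CSV) and grids (CSV + sidecar header), and
aggregates grids onto polygons by exact polygon–rectangle clipping.

## Worked example

```sh
$ urbanscale simulate --seed 3 --outdir demo
wrote demo/cities.csv (50000 cities) and demo/grid.csv

$ urbanscale scaling fit --cities demo/cities.csv --measure e_co2
e_co2: conditional-mean exponent = 0.7919 +/- 0.0114 (r^2=0.9961, window P in [1e+03, 2.59e+06])
e_co2: all-data exponent = 0.8010 +/- 0.0052

$ urbanscale scaling collapse --cities demo/cities.csv --measure e_co2 --exponent 0.81
collapse quality at exponent 0.81: 0.04640
```

The simulated cities were generated with a true conditional exponent of
0.81 and half a decade of lognormal scatter; the conditional-mean fit
recovers 0.79 ± 0.01 with the selected fit window reported for audit, and
the all-data estimator agrees here because the scatter is homoscedastic in
the log domain.  The collapse quality is the between-curve variance of
log-density over the shared support of the rescaled conditional
distributions — small at the true exponent and strictly larger at a wrong
one.

The cascade grid written next to the city table is the multifractal oracle:

```python
>>> from urbanscale import synthetic, multifractal
>>> g = synthetic.generate_cascade(synthetic.CascadeConfig(depth=8, weights=(0.4, 0.3, 0.2, 0.1)))
>>> _, spec = multifractal.analyze_grid(g)
tau(2) = 1.7370  (closed form 1.7370)
D_2    = 1.7370
```

`urbanscale run-all --seed 11 --outdir out` chains every stage (simulate →
fit → collapse → box counting → correlations) and writes all intermediate
CSVs, a JSON report and the resolved configuration; identical seed and
configuration give byte-identical outputs.

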