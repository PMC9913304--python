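# survtrend

Age-standardized net-survival estimation and Bayesian trend analysis for
cancer-registry-style data, exercised end-to-end on synthetic registries.

The package implements a five-stage pipeline:

1. **`survtrend.synthetic`** — synthetic registry generation: Gompertz–Makeham
   life tables, individual-level cohorts whose excess hazard follows a
   configurable calendar-time trend (constant / linear / logistic /
   piecewise-linear ground truths), age-specific rate tables, and period-wise
   survival estimates with per-point standard errors.
2. **`survtrend.netsurv`** — net (relative) survival estimation with the
   inverse-expected-survival-weighted estimator (Pohar Perme), external-weight
   age standardization over ages 0–89, cohort and hybrid (delayed-entry)
   period designs, and CI↔SE conversion for registry exports.
3. **`survtrend.rates`** — world-standard age-standardized rates, cumulative
   risk (ages 0–74) and a cubic penalized-spline smoother for display.
4. **`survtrend.trend`** — a Gaussian measurement-error spline model for
   period survival estimates (identity link, per-point SDs fixed at the
   reported SEs, shared 5-knot penalized basis with group effects and
   group-specific smooths; flat intercept, Normal(0, 20) group-effect prior).
   The default engine integrates the smoothing scale by quadrature over its
   exact Gaussian conditional posterior; a blocked Gibbs sampler
   (`method="gibbs"`, 2 chains × 7000 iterations with 2000 warm-up by
   default) is available for parity checks. Split-R̂ / ESS diagnostics are
   attached to every fit.
5. **`survtrend.features`** — posterior 5/1-year conditional survival
   (per-draw ratio of paired draws), annual change (analytic first-derivative
   draws summarized pointwise), plausible-trend intervals (95 % CI of the
   first derivative excluding zero for ≥ 5 years) and breaking points (peak
   |median second derivative| within ≥ 3-year runs where the second
   derivative's 95 % CI excludes zero).

`survtrend.io`, `survtrend.pipeline`, `survtrend.plotting` and the CLI tie
the stages together with plain CSV/JSON/YAML interchange formats and
per-site figure panels (solid segments for plausible trends, vertical
breakpoint lines, annual-change strip).

## CLI

```bash
survtrend init-config demo.yaml      # write the built-in demo configuration
survtrend run --config demo.yaml --seed 1 --out out/
# or stage by stage (stages compose through the output directory):
survtrend simulate --config demo.yaml --out out/
survtrend trend    --config demo.yaml --out out/
survtrend features --config demo.yaml --out out/
survtrend report   --config demo.yaml --out out/
```

Outputs: `survival_points.csv` (registry-export dialect), `life_table.csv`,
`rate_tables.csv`, per-site posterior curve sets (`curves_*.npz`), feature
JSON / annual-change CSV, and PNG/SVG panels. Every artifact embeds the
run's config hash and seed; reruns with the same config and seed are
byte-identical for the JSON outputs.

## Layout

```
src/survtrend/
  datatypes.py   core containers (LifeTable, IndividualRecord, SurvivalPoint, …)
  synthetic.py   generators for cohorts, life tables, rates, survival points
  netsurv.py     net-survival estimator, age standardization, period designs
  rates.py       ASR, cumulative risk, display smoothing
  trend.py       spline basis + measurement-error trend model
  features.py    conditional ratio, annual change, intervals, breakpoints
  io.py          CSV/JSON readers & writers
  pipeline.py    staged pipeline + run configuration
  plotting.py    figure panels
  cli.py         click CLI
  data/          replaceable weight tables (survival & world standards)
tests/           pytest suite incl. brute-force oracles and acceptance tests
scripts/         acceptance report
```
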