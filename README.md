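# elebench

**Ecological benchmarks for savanna elephant populations.**

Protected-area elephant counts are abundant, but on their own they lack
context: how many elephants *should* a given protected area hold? `elebench`
answers that question by (1) extracting environmentally mediated stable
densities from count time series, (2) modeling those densities as a smooth
function of primary productivity, water availability and poaching pressure,
and (3) predicting each area's **ecological benchmark** — the stable
population size expected under a scenario of zero poaching — together with
the deficit between recent counts and that benchmark, all with full Monte
Carlo uncertainty propagation.

The package is aimed at quantitative ecologists and conservation analysts
working with wildlife count time series, carcass-monitoring data (PIKE:
proportion of illegally killed elephants) and protected-area covariates.

## The model

1. **Stable densities.** Each count series (density N(t) = estimate/area)
   is fit by least squares to five candidate trajectories — null (N = K),
   linear, exponential, logistic and Gompertz — and the best is chosen by
   AICc. Null-selected populations fluctuate around an equilibrium; their
   level K is the stable density, with an SE from a 1,000-draw Monte Carlo
   over count uncertainty.

2. **Poaching intensity.** PIKE is estimated empirically at carcass-
   monitored sites (counts amalgamated over 2002–2014, sites with < 20
   carcasses excluded) and predicted elsewhere by a QAICc-averaged set of
   quasi-binomial GLMs on site covariates.

3. **The benchmark GAM.** Stable sizes follow a negative-binomial GAM,
   `log E[size] = β₀ + f(EVI) + f(water) + f(PIKE) + log(area)`, with
   rank-3 thin-plate smooths (≤ 3 knots per covariate), GCV-selected
   smoothing, ML-estimated dispersion θ (variance μ + μ²/θ), AICc candidate
   selection, leave-one-out cross-validation (cvCOR, Willmott's D, MBE) and
   hat/Cook influence diagnostics.

4. **Scenarios and uncertainty.** The GAM predicts each area's stable size
   under current PIKE and under PIKE = 0 (the benchmark); deficits are
   recent − benchmark. A nested Monte Carlo (outer: redraw stable densities
   and modeled PIKE, refit the GAM; inner: simulate GAM coefficients)
   yields medians, SEs and asymmetric 95% prediction intervals for every
   prediction, deficit and total.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Everything runs on synthetic data with known ground truth (no field data
ship with the package). The one-liner below simulates a 73-area continental
study and runs every stage:

```python
import elebench as eb

cfg = eb.RunConfig(outdir="run", seed=7, n_robustness_sims=100,
                   n_outer=20, n_inner=20)
res = eb.run_pipeline(cfg)

h = res["headlines"]
print(res["selection_report"]["best_model"].value_counts().to_dict())
print(res["gam_selection"][["formula_id", "aicc", "weight", "selected"]])
print(f"areas in deficit: {h['n_deficit']} of {h['n_areas']}")
print(f"median % of benchmark: {h['median_pct_of_benchmark']:.1f}")
print(f"net deficit: {h['net_deficit']:,.0f}")
```

Output from this exact run:

```
{'null': 18, 'exponential': 3, 'linear': 1, 'logistic': 1}
       formula_id        aicc        weight  selected
0            null  363.299516  1.103446e-21     False
1       evi_water  270.248437  1.772295e-01     False
2  evi_water_pike  267.177974  8.227705e-01      True
areas in deficit: 70 of 73
median % of benchmark: 42.0
net deficit: -618,237
```

Reading it: of 23 eligible time series, 18 are at equilibrium (null model)
and supply stable densities; the GAM including the poaching covariate wins
the AICc comparison (weight 0.82); 70 of 73 areas hold fewer elephants than
their zero-poaching benchmark, with ~618,000 elephants missing network-wide
in this synthetic world. `run/` then contains every stage table
(`selection_report.csv`, `stable_densities.csv`, `pike_estimates.csv`,
`gam_selection.csv`, `benchmarks.csv`, `mc_summary.csv`, `headlines.json`,
`run_report.json`).

The `examples/` scripts walk the stages one at a time, and a thin CLI
(`elebench run-all --seed 7 --outdir run`) wraps the same pipeline for
shell use.

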