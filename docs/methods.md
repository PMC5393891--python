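# Methods

`elebench` estimates how many savanna elephants a protected area would hold
if ecological conditions, rather than poaching, set its equilibrium. The
pipeline has five stages; this note records the model in each stage, its
assumptions, the tunable parameters, and the numerical and design choices
made where more than one reasonable option existed.

## 1. Stable densities from count time series

Under natural conditions an elephant population drifts toward, and then
fluctuates around, an environmentally mediated equilibrium density. To find
populations in that state we fit five candidate trajectories to each
eligible count series, on the density scale (estimate / area, elephants/km²)
against years since the first count:

| model | form | parameters |
|---|---|---|
| null | N(t) = K | K |
| linear | N(t) = a + b·t | a, b |
| exponential | N(t) = N₀·e^{r·t} | N₀, r |
| logistic | N(t) = K / (1 + ((K−N₀)/N₀)·e^{−r·t}) | K, N₀, r |
| Gompertz | N(t) = K·exp(ln(N₀/K)·e^{−r·t}) | K, N₀, r |

Eligibility: at least five counts of survey-reliability class A or B since
1989 and a population of at least 500 animals. Fits are least squares;
nonlinear models use Levenberg–Marquardt on log-transformed K and N₀
(positivity) with multi-start initialization (K₀ = mean of the last three
densities, N₀ = first density, r₀ ∈ {0.01, 0.05, 0.1}; for the exponential
model a log-linear regression provides the rate start). Model choice is by
least-squares AICc, n·ln(RSS/n) + 2k + 2k(k+1)/(n−k−1), where k counts the
residual-variance parameter (null 2, linear/exponential 3,
logistic/Gompertz 4). A model with n ≤ k+1 is inadmissible for that series;
an exact fit (RSS = 0) dominates any comparison; exact ties break toward
fewer parameters. Series best described by linear or exponential change are
not at equilibrium and are excluded from training.

Counts carry survey error. Robustness and extraction uncertainty come from
a Monte Carlo: each count is redrawn from a normal distribution with its
reported SE, truncated at zero (counts cannot be negative; total counts
have SE = 0 and are never perturbed), model selection is repeated, and the
originally selected model is refit to every simulated series. Robustness is
the fraction of runs re-selecting the original winner; the stable density
and its SE are the mean and SD of the refit equilibrium level K. Per-run
refits warm-start from the original parameters, which is both faster and
appropriate since each simulated series differs only by survey noise. A
null-selected series additionally gets an ordinary least-squares test of
density on year; equilibrium populations should show no significant trend.

## 2. Poaching intensity (PIKE)

PIKE — the proportion of illegally killed elephants — is the ratio of
illegal to total carcasses found at a monitored site. Counts are summed per
site over the 2002–2014 monitoring window to damp year-to-year carcass
noise, and sites with fewer than 20 amalgamated carcasses are dropped as
too noisy. Where a protected area has no carcass monitoring, PIKE is
predicted from site covariates by a set of quasi-binomial GLMs (logit link,
weighted by total carcasses, Pearson-χ² dispersion, t-based inference as is
conventional when the dispersion is estimated). Candidate predictor subsets
come from configuration (all subsets of the covariate pool by default);
they are compared by QAICc, using the global model's dispersion estimate
and counting the dispersion as a parameter, and combined by full-model
averaging: Akaike weights applied to coefficient vectors with zeros for
absent terms. A prediction's linear-predictor SE is the unconditional
model-averaging form √(Σ w_m (var_m + (η_m − η̄)²)), which carries
between-model spread into downstream simulation. Empirical PIKE values are
kept as-is; a continuity-corrected logit SE is attached for completeness
but empirical PIKE is held fixed in the Monte Carlo — only modeled values
are uncertain inputs.

## 3. The stable-density GAM

Stable population sizes (density × area, rounded to the nearest integer
since the negative binomial has integer support) are modeled as

  size_i ~ NB(μ_i, θ),  log μ_i = β₀ + f₁(EVI_i) + f₂(water_i) + f₃(PIKE_i) + ln A_i

with variance μ + μ²/θ and ln A (log area, km²) as an offset, so the model
is equivalently one of density and predicted size is exactly proportional
to area at fixed covariates. Each smooth f_j is a rank-3 thin-plate
regression spline: the cubic radial penalty matrix E_ij = |x_i − x_j|³ is
projected orthogonal to the {1, x} null space and eigendecomposed, and the
leading eigenvector joins the linear term as one penalized basis column
(eigenvalue = its penalty). Three knots per covariate is a deliberately
tight cap: with 18 training points, anything more flexible overfits.
Columns are centred for identifiability with the global intercept and
scaled for conditioning.

Fitting is penalized IRLS with step halving. Smoothing parameters minimize
GCV, n·D/(n − EDF)², by Nelder–Mead on log λ (an explicit initial simplex
with 3-log-unit steps, since λ must be explored across orders of
magnitude); θ is then re-estimated by maximizing the NB likelihood at the
current fit, and the two steps alternate to convergence. The coefficient
posterior is the usual penalized-fit approximation N(β̂, (XᵀWX + S_λ)⁻¹).
Reported fit statistics: deviance explained (against an intercept-plus-
offset NB fit at the same θ), R² and adjusted R² (squared Pearson
correlation of observed and fitted sizes, adjusted with EDF as the
parameter count), and AICc with k = EDF + 1 (the dispersion).

Three candidate formulas are compared — intercept-only, EVI + water, and
EVI + water + PIKE — by AICc, with leave-one-out cross-validation metrics
reported per candidate: cvCOR (Pearson r of held-out predictions and
observations), Willmott's index of agreement D = 1 − Σ(P−O)² /
Σ(|P−Ō|+|O−Ō|)², and mean bias error. LOOCV is computed on the response
(size) scale — the scale the model is fit on. Influence diagnostics use the
hat diagonal of the penalized smoother matrix (high leverage: hat > 3 ×
mean hat) and a GLM-form Cook's distance with EDF as the parameter count
(influential: D > 1); a sensitivity refit drops any flagged row and
correlates predictions with the full fit.

Cross-check: on a fixed synthetic training set, fitted values from this
implementation correlate > 0.99 with an mgcv fit of the same specification
(`s(x, k = 3)` per covariate, `family = nb()`, log-area offset), with the
dispersion in the same range; the test suite runs this comparison.

## 4. Scenarios and deficits

The selected GAM predicts each area's stable size under its current PIKE
(empirical or modeled) and under PIKE = 0 — the **ecological benchmark**:
the population expected if poaching, but not ecology, were removed.
Predictions at covariates outside the training range are flagged as
extrapolation but not suppressed. Deficit accounting is pure arithmetic:
deficit = recent estimate − benchmark (negative = missing elephants), with
the identity Σ deficits = Σ recent − Σ benchmark holding exactly. Headline
summaries include the median recent-to-benchmark percentage, counts of
areas at ≤5%, ≤10% and ≥75% of benchmark, the cumulative percentage,
Spearman rank correlation of recent estimates with current-conditions
predictions, an OLS of recent density on benchmark density, and the
concentration of the ten largest deficits.

## 5. Nested Monte Carlo uncertainty

Three uncertainty sources propagate to every prediction: (i) SEs of the
extracted stable densities, (ii) linear-predictor SEs of modeled PIKE,
(iii) GAM coefficient uncertainty. Outer loop (default 1000, tests and
examples use 100): redraw training densities from zero-truncated normals
and modeled PIKE from logit-scale normals, refit the GAM (same formula,
GCV warm-started at the point fit's λ, θ re-estimated, held fixed within
the inner loop). Inner loop (default 1000): draw coefficients from each
refit's posterior and predict all areas under both scenarios. Deficits and
network totals are computed inside each draw — never from per-area
summaries — and medians, SDs and asymmetric 95% intervals (2.5th/97.5th
empirical percentiles, linear interpolation) are read off the pooled
n_outer × n_inner draws. With n_inner = 1 the posterior mean replaces the
coefficient draw, so a run with every SE at zero reproduces the
deterministic pipeline exactly (the refit is skipped in that case, since
it would be identical by construction). More than 10% failed refits aborts
the propagation.

### Calibration of the intervals

The nested scheme is intentionally generous rather than calibrated, and
users should know in which direction it errs. When the scatter of training
sizes around the smooth surface is dominated by *known measurement error*
(the SEs fed to the outer loop), the outer perturbation and the coefficient
posterior both express that same sampling noise, so the pooled draws spread
about √2 wider than the sampling distribution of the point prediction;
coverage of the generating surface then runs near 98–99% rather than 95%.
Conversely, when training sizes scatter with strong *ecological
overdispersion* (small θ) beyond the reported SEs, GCV smoothing bias and
upward bias in θ̂ at n = 18 narrow the intervals relative to the truth, and
coverage can fall well below nominal (replicate experiments under θ ≈ 3
show 70–85%). The package's validation experiments
(`elebench.validation.pi_coverage_experiment`) expose both regimes; the
default regime mirrors the end-to-end synthetic study, where extraction
error is the dominant, known noise source.

## The synthetic study

`simulate.SimulationSpec` defines the world the tests run in: 73 protected
areas of 1,020–47,666 km², mean EVI up to 0.404, water proportion 0.1–1.0,
all uniform; a log-linear density surface exp(−1.845 + 4.5·EVI +
1.5·water − 3·PIKE) chosen so zero-poaching densities span roughly
0.23–4.3 elephants/km² (a realistic continental range); PIKE logit-linear
in EVI and water with Poisson carcass totals (12/site-year, 2002–2014) at
60% of areas; 23 areas with count series (18 at equilibrium, 4 in
exponential decline, 1 in linear decline), 8 yearly counts each at 10%
survey CV; stable-size training noise negative-binomial with θ = 3.1.
Recent estimates are a Beta(1.5, 3) fraction of the current-conditions
stable size (series areas use their last count), so most areas sit well
below benchmark. What the generator does *not* emulate: spatial structure
and movement, density dependence in the observation process, seasonal or
climate trends in EVI and water, carcass-detection bias, and age structure.
Passing tests therefore demonstrate statistical correctness of the
machinery, not that real count data meet these assumptions.

## Problem sizes and numerics

Tests and the acceptance script run the Monte Carlo at 100 × 100 (10⁴
draws per area) and validation experiments at 100–300 replicates; these
sizes give Monte Carlo error comfortably below the tolerances asserted
while keeping a full run on one CPU in minutes. The full 1000 × 1000
propagation is a parameter change (`n_outer`, `n_inner`). Degenerate
inputs are handled explicitly: RSS = 0 trajectories select the most
parsimonious exact model; all-zero SEs short-circuit the robustness MC and
the propagation; rank-deficient GAM designs fall back to a pseudoinverse
solve; PIKE candidates that fail (separation, singular design) are dropped
from the average with a log entry.

## Known limitations

- The prediction intervals are not calibrated (see above); they are a
  transparent propagation of stated uncertainties, not a frequentist
  guarantee.
- Empirical PIKE is treated as exact; carcass detection bias is outside
  scope.
- The rank-3 basis cannot represent sharp nonlinearity; with richer
  training data the knot cap should be revisited alongside the training-set
  size.
- AICc comparison across NB GAMs treats EDF as the parameter count and
  conditions on the selected θ per candidate; both are conventions, not
  exact small-sample theory.
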