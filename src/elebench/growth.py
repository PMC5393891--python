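"""Growth-model selection and stable-density extraction from count time series.

Each eligible elephant count time series (density = estimate / area) is fit by
nonlinear least squares to five candidate trajectory models — null (no trend),
linear, exponential, logistic and Gompertz — and the best model is chosen by
AICc. Populations whose best model is the null are taken to fluctuate around an
environmentally mediated equilibrium; the null-model level K is the "stable
density". Uncertainty in the counts is propagated by a Monte Carlo in which
each count is redrawn from a normal distribution (truncated at zero) with its
reported standard error, the winning model is refit to every simulated series,
and the spread of the refit K gives the stable density's standard error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

MODEL_IDS = ("null", "linear", "exponential", "logistic", "gompertz")

#: number of least-squares parameters per model, counting the residual
#: variance (null: K + sigma; linear: a, b + sigma; exponential: N0, r + sigma;
#: logistic/gompertz: K, N0, r + sigma)
MODEL_K = {"null": 2, "linear": 3, "exponential": 3, "logistic": 4, "gompertz": 4}


@dataclass
class CountTimeSeries:
    """Yearly (estimate, SE, reliability) records for one protected area."""

    area_id: str
    years: np.ndarray          # strictly increasing integers
    estimates: np.ndarray      # elephants, >= 0
    ses: np.ndarray            # elephants, >= 0 (0 for total counts)
    reliabilities: np.ndarray  # survey reliability class 'A'..'E'
    area_km2: float

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=float)
        self.estimates = np.asarray(self.estimates, dtype=float)
        self.ses = np.asarray(self.ses, dtype=float)
        self.reliabilities = np.asarray(self.reliabilities, dtype=object)
        if len(self.years) < 1:
            raise ValueError("time series needs at least one record")
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if np.any(self.estimates < 0) or np.any(self.ses < 0):
            raise ValueError("estimates and SEs must be non-negative")
        if self.area_km2 <= 0:
            raise ValueError("area_km2 must be positive")

    @property
    def n(self) -> int:
        return len(self.years)

    @property
    def densities(self) -> np.ndarray:
        return self.estimates / self.area_km2

    def t(self) -> np.ndarray:
        """Years since the first count."""
        return self.years - self.years[0]


@dataclass
class GrowthFit:
    model_id: str
    params: dict
    rss: float
    n: int
    k: int
    aicc: float
    converged: bool


@dataclass
class ModelSelection:
    area_id: str
    fits: dict                 # model_id -> GrowthFit
    best_model_id: str
    delta_aicc: dict           # model_id -> AICc - min AICc (inf if inadmissible)
    robustness: float | None = None
    linear_trend_p: float | None = None


@dataclass
class StableDensityEstimate:
    area_id: str
    density: float             # elephants / km^2
    se: float
    n_sims: int


# ---------------------------------------------------------------------------
# model curves

def evaluate_model(model_id: str, params: dict, t: np.ndarray) -> np.ndarray:
    """Density trajectory of a candidate model at times t (years since start).

    null:        K
    linear:      a + b t
    exponential: N0 exp(r t)
    logistic:    K / (1 + ((K - N0)/N0) exp(-r t))
    gompertz:    K exp(ln(N0/K) exp(-r t))
    """
    t = np.asarray(t, dtype=float)
    if model_id == "null":
        return np.full_like(t, float(params["K"]))
    if model_id == "linear":
        return params["a"] + params["b"] * t
    if model_id == "exponential":
        if params["N0"] <= 0:
            raise ValueError("exponential model requires N0 > 0")
        return params["N0"] * np.exp(params["r"] * t)
    if model_id == "logistic":
        K, N0, r = params["K"], params["N0"], params["r"]
        if N0 <= 0 or K <= 0:
            raise ValueError("logistic model requires K, N0 > 0")
        return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))
    if model_id == "gompertz":
        K, N0, r = params["K"], params["N0"], params["r"]
        if N0 <= 0 or K <= 0:
            raise ValueError("gompertz model requires K, N0 > 0")
        return K * np.exp(np.log(N0 / K) * np.exp(-r * t))
    raise ValueError(f"unknown model_id {model_id!r}")


def aicc(rss: float, n: int, k: int) -> float:
    """Least-squares AICc: n ln(rss/n) + 2k + 2k(k+1)/(n-k-1).

    rss = 0 maps to -inf (a perfect fit dominates any comparison);
    n <= k + 1 makes the model inadmissible (+inf).
    """
    if n <= k + 1:
        return math.inf
    if rss <= 0.0:
        return -math.inf
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# eligibility

def filter_eligible_series(
    all_series: list[CountTimeSeries],
    min_pop: float = 500.0,
    min_counts: int = 5,
    min_year: int = 1989,
    reliability: frozenset = frozenset({"A", "B"}),
) -> list[CountTimeSeries]:
    """Keep series with >= min_counts reliable counts since min_year and a
    population of at least min_pop elephants.

    Only counts from min_year onwards with reliability in the accepted set
    contribute; the filtered series returned contain just those records. The
    population-size criterion is judged on the most recent retained estimate.
    """
    eligible = []
    for s in all_series:
        keep = (s.years >= min_year) & np.isin(s.reliabilities.astype(str), list(reliability))
        if keep.sum() < min_counts:
            continue
        sub = CountTimeSeries(
            area_id=s.area_id,
            years=s.years[keep],
            estimates=s.estimates[keep],
            ses=s.ses[keep],
            reliabilities=s.reliabilities[keep],
            area_km2=s.area_km2,
        )
        if sub.estimates[-1] < min_pop:
            continue
        eligible.append(sub)
    return eligible


# ---------------------------------------------------------------------------
# fitting

def _fit_null(t: np.ndarray, d: np.ndarray) -> tuple[dict, float]:
    K = float(np.mean(d))
    rss = float(np.sum((d - K) ** 2))
    return {"K": K}, rss


def _fit_linear(t: np.ndarray, d: np.ndarray) -> tuple[dict, float]:
    X = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(X, d, rcond=None)
    resid = d - X @ coef
    return {"a": float(coef[0]), "b": float(coef[1])}, float(resid @ resid)


def _nls(model_id: str, t: np.ndarray, d: np.ndarray,
         starts: list[dict]) -> tuple[dict, float, bool]:
    """Levenberg-Marquardt in transformed (log) parameters.

    K, N0 are fit on the log scale (positivity); r is unconstrained for the
    exponential model and log-scale for the asymptotic models (growth toward
    K; decline toward K is still covered via N0 > K).
    """
    names = {"exponential": ("N0", "r"),
             "logistic": ("K", "N0", "r"),
             "gompertz": ("K", "N0", "r")}[model_id]
    log_scale = {"K": True, "N0": True,
                 "r": model_id != "exponential"}

    def unpack(theta):
        return {nm: (math.exp(v) if log_scale[nm] else v)
                for nm, v in zip(names, theta)}

    def resid(theta):
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            pred = evaluate_model(model_id, unpack(theta), t)
        return np.where(np.isfinite(pred), pred, 1e12) - d

    best = None
    for s0 in starts:
        x0 = np.array([math.log(max(s0[nm], 1e-8)) if log_scale[nm] else s0[nm]
                       for nm in names])
        try:
            sol = optimize.least_squares(resid, x0, method="lm", max_nfev=120,
                                         xtol=1e-10)
        except Exception:
            continue
        rss = float(2.0 * sol.cost)
        if np.all(np.isfinite(sol.x)) and (best is None or rss < best[1]):
            best = (unpack(sol.x), rss)
    if best is None:
        return {}, math.inf, False
    return {k: float(v) for k, v in best[0].items()}, best[1], True


def fit_model(series: CountTimeSeries, model_id: str,
              start_hint: dict | None = None) -> GrowthFit:
    """Least-squares fit of one candidate model to the density series.

    Multi-start initialization: K0 = mean of the last three densities,
    N0_0 = first density, r0 in {0.01, 0.05, 0.1}, linear slope from OLS.
    `start_hint` (parameters of a previous fit to similar data) replaces the
    default start grid, as in the count-uncertainty Monte Carlo where each
    simulated series differs from the original only by survey noise.
    """
    t = series.t()
    d = series.densities
    n = series.n
    k = MODEL_K[model_id]
    eps = 1e-10

    if model_id == "null":
        params, rss = _fit_null(t, d)
        conv = True
    elif model_id == "linear":
        params, rss = _fit_linear(t, d)
        conv = True
    else:
        d0 = max(float(d[0]), eps)
        K0 = max(float(np.mean(d[-3:])), eps)
        r0s = (0.01, 0.05, 0.1)
        if start_hint is not None:
            starts = [start_hint]
        elif model_id == "exponential":
            # log-linear start when all densities positive, else spec r0 grid
            if np.all(d > 0):
                slope = float(np.polyfit(t, np.log(d), 1)[0])
                starts = [{"N0": d0, "r": slope}, {"N0": d0, "r": 0.05}]
            else:
                starts = [{"N0": d0, "r": r} for r in r0s]
        else:
            starts = [{"K": K0, "N0": d0, "r": r} for r in r0s]
        params, rss, conv = _nls(model_id, t, d, starts)

    a = aicc(rss, n, k) if conv else math.inf
    return GrowthFit(model_id=model_id, params=params, rss=rss, n=n, k=k,
                     aicc=a, converged=conv)


def select_best_model(series: CountTimeSeries,
                      start_hints: dict | None = None) -> ModelSelection:
    """Fit all five candidates and pick the minimum-AICc model.

    Models with n <= k + 1 are inadmissible and excluded. Ties (equal AICc)
    break toward the model with fewer parameters.
    """
    fits = {m: fit_model(series, m, start_hint=(start_hints or {}).get(m))
            for m in MODEL_IDS}
    admissible = {m: f for m, f in fits.items()
                  if f.converged and f.aicc < math.inf}
    if not admissible:
        raise RuntimeError(f"no admissible model fit for series {series.area_id}")
    best = min(admissible, key=lambda m: (admissible[m].aicc, admissible[m].k))
    amin = admissible[best].aicc
    if amin == -math.inf:
        # one or more perfect (rss = 0) fits: they tie at -inf, parsimony wins
        delta = {m: (0.0 if admissible.get(m, None) and fits[m].aicc == -math.inf
                     else math.inf) for m in MODEL_IDS}
    else:
        delta = {m: (fits[m].aicc - amin if m in admissible else math.inf)
                 for m in MODEL_IDS}
    return ModelSelection(area_id=series.area_id, fits=fits,
                          best_model_id=best, delta_aicc=delta)


def test_linear_trend(series: CountTimeSeries) -> float:
    """Two-sided p-value for the OLS slope of density on year."""
    if series.n < 3:
        raise ValueError("need at least 3 counts to test a linear trend")
    if np.ptp(series.years) == 0:
        raise ValueError("zero variance in year")
    d = series.densities
    if np.allclose(d, d[0]):
        return 1.0
    res = stats.linregress(series.years, d)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# count-uncertainty Monte Carlo

def _simulate_series(series: CountTimeSeries, rng: np.random.Generator) -> CountTimeSeries:
    """Redraw each count from Normal(estimate, SE) truncated at zero."""
    est = series.estimates.copy()
    pos = series.ses > 0
    if pos.any():
        m, s = series.estimates[pos], series.ses[pos]
        a = (0.0 - m) / s
        est[pos] = stats.truncnorm.rvs(a, np.inf, loc=m, scale=s, random_state=rng)
    return CountTimeSeries(series.area_id, series.years, est, series.ses,
                           series.reliabilities, series.area_km2)


def assess_robustness(
    series: CountTimeSeries,
    n_sims: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float, float]:
    """Robustness of model selection under count uncertainty.

    Simulates n_sims replicate series (normal draws per count, truncated at 0),
    re-selects the best model for each, and reports the proportion matching the
    original selection. The originally selected model is refit to every
    simulated series; the mean and SD of its equilibrium level K over the runs
    give the stable density and its SE (only meaningful when the original best
    model is the null). Runs that fail to converge are dropped.

    Returns (robustness, stable_density, stable_density_se).
    """
    rng = np.random.default_rng(seed)
    original = select_best_model(series)
    best = original.best_model_id

    if np.all(series.ses == 0):
        # degenerate MC: every replicate equals the original data
        K = original.fits["null"].params.get("K", np.nan)
        return 1.0, float(K), 0.0

    # warm-start every per-simulation refit from the original fits
    hints = {m: f.params for m, f in original.fits.items()
             if f.converged and m not in ("null", "linear")}
    matches = 0
    Ks = []
    n_done = 0
    for _ in range(n_sims):
        sim = _simulate_series(series, rng)
        try:
            sel = select_best_model(sim, start_hints=hints)
        except RuntimeError:
            continue
        n_done += 1
        if sel.best_model_id == best:
            matches += 1
        refit = sel.fits[best]
        if refit.converged and "K" in refit.params:
            Ks.append(refit.params["K"])
    robustness = matches / n_done if n_done else np.nan
    if Ks:
        density = float(np.mean(Ks))
        se = float(np.std(Ks, ddof=1)) if len(Ks) > 1 else 0.0
    else:
        density, se = np.nan, np.nan
    return robustness, density, se


# ---------------------------------------------------------------------------
# whole-dataset driver

def extract_stable_densities(
    series_list: list[CountTimeSeries],
    n_sims: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run selection + robustness over all eligible series.

    Returns (selection_report, stable_densities). The report has one row per
    series with per-model AICc, the best model, robustness and the linear-trend
    p-value; stable densities are extracted only for null-selected series.
    """
    ss = np.random.SeedSequence(seed) if isinstance(seed, int) else seed
    children = ss.spawn(len(series_list))
    report_rows, stable_rows = [], []
    for s, child in zip(series_list, children):
        sel = select_best_model(s)
        p_lin = test_linear_trend(s) if s.n >= 3 else np.nan
        rob, dens, dens_se = assess_robustness(s, n_sims=n_sims, seed=child)
        row = {"area_id": s.area_id, "n_counts": s.n,
               "best_model": sel.best_model_id,
               "robustness": rob, "linear_trend_p": p_lin}
        for m in MODEL_IDS:
            row[f"aicc_{m}"] = sel.fits[m].aicc
            row[f"delta_aicc_{m}"] = sel.delta_aicc[m]
        report_rows.append(row)
        if sel.best_model_id == "null":
            stable_rows.append({"area_id": s.area_id, "density": dens,
                                "se": dens_se, "n_sims": n_sims})
    return pd.DataFrame(report_rows), pd.DataFrame(stable_rows)
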