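"""Scenario prediction, deficit accounting and headline summaries.

Given the fitted stable-density GAM, each protected area gets a predicted
stable population size under its current poaching level and under a
zero-poaching scenario (PIKE = 0), the "ecological benchmark". Subtracting
the benchmark from the most recent population estimate yields the per-area
deficit (negative = missing elephants); headline statistics summarize how
far the network sits below its benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gam import GamFit

REQUIRED_COVS = ("evi", "prop_12_water", "area_km2")


def predict_scenario(
    fit: GamFit,
    areas: pd.DataFrame,
    pike_override: float | None = None,
    scenario: str | None = None,
) -> pd.DataFrame:
    """Response-scale stable-size predictions for every area.

    `areas` needs evi, prop_12_water, area_km2 and — unless `pike_override`
    is given — a pike column (empirical or modeled). `pike_override = 0`
    is the ecological-benchmark scenario. Predictions outside the training
    covariate range are flagged as extrapolation.
    """
    for c in REQUIRED_COVS:
        if c not in areas.columns or areas[c].isna().any():
            bad = "" if c not in areas.columns else \
                f" (areas {list(areas.loc[areas[c].isna(), 'area_id'][:5])})"
            raise ValueError(f"missing covariate {c!r}{bad}")
    data = areas.copy()
    if pike_override is not None:
        data["pike"] = float(pike_override)
    elif "pike" in fit.terms and ("pike" not in data.columns or data["pike"].isna().any()):
        bad = [] if "pike" not in data.columns else \
            list(data.loc[data["pike"].isna(), "area_id"][:5])
        raise ValueError(f"missing PIKE for areas {bad}")
    if scenario is None:
        scenario = "zero_pike" if pike_override == 0 else "current_pike"

    log_area = np.log(data["area_km2"].to_numpy(dtype=float))
    if "pike" not in data.columns:
        data["pike"] = 0.0  # ignored unless the formula includes it
    size = fit.predict_size(data, log_area)
    return pd.DataFrame({
        "area_id": data["area_id"].to_numpy(),
        "scenario": scenario,
        "predicted_size": size,
        "predicted_density": size / data["area_km2"].to_numpy(dtype=float),
        "extrapolation_flag": fit.extrapolation_flags(data),
    })


@dataclass
class DeficitTotals:
    total_recent: float
    total_benchmark: float
    net_deficit: float          # total_recent - total_benchmark (negative = missing)
    n_deficit: int
    n_surplus: int


def compute_deficits(benchmarks: pd.DataFrame,
                     recent: pd.DataFrame) -> tuple[pd.DataFrame, DeficitTotals]:
    """Per-area deficit records: recent estimate minus benchmark size.

    `benchmarks` is a predict_scenario frame (zero-PIKE); `recent` needs
    area_id and recent_estimate. Every area must match.
    """
    merged = benchmarks.merge(recent[["area_id", "recent_estimate"]],
                              on="area_id", how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", "area_id"].tolist()
        raise ValueError(f"unmatched area ids: {bad[:5]}")
    out = pd.DataFrame({
        "area_id": merged["area_id"],
        "recent_estimate": merged["recent_estimate"].astype(float),
        "benchmark_size": merged["predicted_size"].astype(float),
    })
    out["deficit"] = out["recent_estimate"] - out["benchmark_size"]
    out["pct_of_benchmark"] = 100.0 * out["recent_estimate"] / out["benchmark_size"]
    totals = DeficitTotals(
        total_recent=float(out["recent_estimate"].sum()),
        total_benchmark=float(out["benchmark_size"].sum()),
        net_deficit=float(out["deficit"].sum()),
        n_deficit=int((out["deficit"] < 0).sum()),
        n_surplus=int((out["deficit"] >= 0).sum()),
    )
    return out, totals


def summarize_headlines(deficits: pd.DataFrame, totals: DeficitTotals,
                        predictions_current: pd.DataFrame,
                        areas: pd.DataFrame, top_k: int = 10) -> dict:
    """Headline statistics of the deficit accounting.

    Includes the median recent density as a percentage of benchmark, counts
    of areas at <=5%, <=10% and >=75% of benchmark, the cumulative
    percentage, Spearman rank correlation between recent estimates and
    current-conditions predictions, an OLS of recent density on benchmark
    density, and the concentration of the top-k deficits.
    """
    pct = deficits["pct_of_benchmark"].to_numpy(dtype=float)
    merged = deficits.merge(
        predictions_current[["area_id", "predicted_size", "predicted_density"]]
        .rename(columns={"predicted_size": "current_size",
                         "predicted_density": "current_density"}),
        on="area_id").merge(areas[["area_id", "area_km2"]], on="area_id")
    rs = stats.spearmanr(merged["recent_estimate"], merged["current_size"])

    recent_density = merged["recent_estimate"] / merged["area_km2"]
    bench_density = merged["benchmark_size"] / merged["area_km2"]
    ols = stats.linregress(bench_density, recent_density)
    n = len(merged)
    f_stat = ols.rvalue**2 / (1 - ols.rvalue**2) * (n - 2) if abs(ols.rvalue) < 1 else np.inf

    shortfalls = np.maximum(-deficits["deficit"].to_numpy(dtype=float), 0.0)
    order = np.argsort(shortfalls)[::-1]
    top = float(shortfalls[order[:top_k]].sum())
    rest = float(shortfalls[order[top_k:]].sum())

    return {
        "n_areas": n,
        "n_deficit": totals.n_deficit,
        "n_surplus": totals.n_surplus,
        "total_recent": totals.total_recent,
        "total_benchmark": totals.total_benchmark,
        "total_current_prediction": float(predictions_current["predicted_size"].sum()),
        "net_deficit": totals.net_deficit,
        "median_pct_of_benchmark": float(np.median(pct)),
        "min_pct_of_benchmark": float(np.min(pct)) if n else np.nan,
        "n_pct_le_5": int((pct <= 5.0).sum()),
        "n_pct_le_10": int((pct <= 10.0).sum()),
        "n_pct_ge_75": int((pct >= 75.0).sum()),
        "cumulative_pct_of_benchmark":
            100.0 * totals.total_recent / totals.total_benchmark,
        "spearman_recent_vs_current": float(rs.statistic),
        "spearman_p": float(rs.pvalue),
        "ols_slope": float(ols.slope),
        "ols_intercept": float(ols.intercept),
        "ols_r2": float(ols.rvalue**2),
        "ols_f": float(f_stat),
        "topk_deficit_sum": top,
        "rest_deficit_sum": rest,
        "top_k": top_k,
    }
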