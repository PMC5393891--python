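"""End-to-end orchestration: simulate → trends → PIKE → GAM → scenarios → MC.

Every stage reads and writes small CSV schemas (areas, counts, carcasses,
stable densities, PIKE estimates, selection tables, benchmarks, MC
summaries), so stages can be rerun or swapped independently. A single
master seed derives per-stage substreams, making a full run bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gam, growth, pike, scenarios, simulate, uncertainty

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "elebench_run"
    seed: int = 0
    # synthetic-data stage (ignored when input paths are given)
    simulate_inputs: bool = True
    areas_csv: str | None = None
    counts_csv: str | None = None
    carcasses_csv: str | None = None
    # eligibility
    min_pop: float = 500.0
    min_counts: int = 5
    min_year: int = 1989
    reliability: tuple = ("A", "B")
    # carcass handling
    carcass_years: tuple = (2002, 2014)
    min_carcasses: int = 20
    pike_covariates: tuple = ("evi", "prop_12_water")
    # growth MC
    n_robustness_sims: int = 1000
    # GAM
    formulas: tuple = ("null", "evi_water", "evi_water_pike")
    # nested MC
    n_outer: int = 100
    n_inner: int = 100

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


def validate_inputs(areas: pd.DataFrame, counts: pd.DataFrame,
                    carcasses: pd.DataFrame) -> list[str]:
    """Schema and range checks; returns a list of violation messages."""
    v: list[str] = []

    def need(df, name, cols):
        missing = set(cols) - set(df.columns)
        if missing:
            v.append(f"{name}: missing columns {sorted(missing)}")
            return False
        return True

    if need(areas, "areas", ["area_id", "area_km2", "evi", "prop_12_water",
                             "recent_estimate"]):
        for i, r in areas.iterrows():
            if r["area_km2"] <= 0:
                v.append(f"areas row {i}: non-positive area_km2")
            for c in ("evi", "prop_12_water"):
                if not 0.0 <= r[c] <= 1.0:
                    v.append(f"areas row {i}: {c} outside [0, 1]")
        if areas["area_id"].duplicated().any():
            v.append("areas: duplicated area_id")
    if need(counts, "counts", ["area_id", "year", "estimate", "se", "reliability"]):
        if (counts["estimate"] < 0).any() or (counts["se"] < 0).any():
            v.append("counts: negative estimate or se")
        dup = counts.duplicated(subset=["area_id", "year"])
        for i in counts.index[dup]:
            v.append(f"counts row {i}: duplicated (area_id, year)")
    if need(carcasses, "carcasses", ["site_id", "year", "illegal_carcasses",
                                     "total_carcasses"]):
        bad = carcasses["illegal_carcasses"] > carcasses["total_carcasses"]
        for i in carcasses.index[bad]:
            v.append(f"carcasses row {i}: illegal > total")
        if (carcasses[["illegal_carcasses", "total_carcasses"]] < 0).any().any():
            v.append("carcasses: negative counts")
    return v


def series_from_counts(counts: pd.DataFrame,
                       areas: pd.DataFrame) -> list[growth.CountTimeSeries]:
    area_km2 = areas.set_index("area_id")["area_km2"]
    out = []
    for aid, sub in counts.groupby("area_id", sort=True):
        sub = sub.sort_values("year")
        out.append(growth.CountTimeSeries(
            area_id=str(aid),
            years=sub["year"].to_numpy(dtype=float),
            estimates=sub["estimate"].to_numpy(dtype=float),
            ses=sub["se"].to_numpy(dtype=float),
            reliabilities=sub["reliability"].to_numpy(dtype=object),
            area_km2=float(area_km2[aid]),
        ))
    return out


def build_training(areas: pd.DataFrame, stable: pd.DataFrame,
                   pike_df: pd.DataFrame) -> pd.DataFrame:
    """Join extracted stable densities with covariates and PIKE."""
    tr = stable.merge(areas, on="area_id", how="inner")
    tr = tr.merge(pike_df[["site_id", "pike"]], left_on="area_id",
                  right_on="site_id", how="left").drop(columns=["site_id"])
    tr["stable_density"] = tr["density"]
    tr["stable_density_se"] = tr["se"]
    tr["stable_size"] = tr["density"] * tr["area_km2"]
    tr["stable_size_se"] = tr["se"] * tr["area_km2"]
    tr["log_area"] = np.log(tr["area_km2"])
    return tr


def run_pipeline(config: RunConfig,
                 sim_spec: simulate.SimulationSpec | None = None) -> dict:
    """Execute every stage and write all outputs under config.outdir.

    Returns a dict with every intermediate table, the fitted models, the
    headline summary and the run report.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.spawn(4)
    stages = []

    # stage 1: inputs
    if config.simulate_inputs and config.areas_csv is None:
        spec = sim_spec or simulate.SimulationSpec(seed=config.seed)
        study = simulate.simulate_study(spec)
        areas, counts, carcasses = study["areas"], study["counts"], study["carcasses"]
        study["truth"].to_csv(outdir / "truth.csv", index=False)
    else:
        areas = pd.read_csv(config.areas_csv)
        counts = pd.read_csv(config.counts_csv)
        carcasses = pd.read_csv(config.carcasses_csv)
        study = {"areas": areas, "counts": counts, "carcasses": carcasses}
    violations = validate_inputs(areas, counts, carcasses)
    if violations:
        raise ValueError("input validation failed: " + "; ".join(violations[:10]))
    areas.to_csv(outdir / "areas.csv", index=False)
    counts.to_csv(outdir / "counts.csv", index=False)
    carcasses.to_csv(outdir / "carcasses.csv", index=False)
    stages.append({"stage": "inputs", "n_areas": len(areas),
                   "n_counts": len(counts), "n_carcass_records": len(carcasses)})

    # stage 2: growth-model selection and stable densities
    all_series = series_from_counts(counts, areas)
    eligible = growth.filter_eligible_series(
        all_series, min_pop=config.min_pop, min_counts=config.min_counts,
        min_year=config.min_year, reliability=frozenset(config.reliability))
    report, stable = growth.extract_stable_densities(
        eligible, n_sims=config.n_robustness_sims, seed=seeds[0])
    report.to_csv(outdir / "selection_report.csv", index=False)
    stable.to_csv(outdir / "stable_densities.csv", index=False)
    stages.append({"stage": "fit-trends", "n_series": len(all_series),
                   "n_eligible": len(eligible), "n_stable": len(stable)})

    # stage 3: PIKE
    pike_df, pike_glm = pike.estimate_all_pike(
        areas, carcasses, covariates=list(config.pike_covariates),
        years=config.carcass_years, min_total=config.min_carcasses)
    pike_df.to_csv(outdir / "pike_estimates.csv", index=False)
    stages.append({"stage": "fit-pike",
                   "n_empirical": int((pike_df["source"] == "empirical").sum()),
                   "n_modeled": int((pike_df["source"] == "modeled").sum()),
                   "dispersion": pike_glm.dispersion})

    # stage 4: GAM selection
    training = build_training(areas, stable, pike_df)
    training.to_csv(outdir / "training.csv", index=False)
    sel_table, fits = gam.select_gam(training, formulas=config.formulas)
    sel_table.to_csv(outdir / "gam_selection.csv", index=False)
    best_id = sel_table.loc[sel_table["selected"], "formula_id"].iloc[0]
    best_fit = fits[best_id]
    diag = gam.diagnostics(best_fit)
    pd.DataFrame({"area_id": training["area_id"], "hat": diag.hat,
                  "cook": diag.cook, "high_leverage": diag.high_leverage,
                  "influential": diag.influential}).to_csv(
        outdir / "diagnostics.csv", index=False)
    stages.append({"stage": "fit-gam", "selected": best_id,
                   "theta": best_fit.theta, "edf": best_fit.edf,
                   "deviance_explained": best_fit.deviance_explained})

    # stage 5: scenario predictions and deficits
    areas_pike = areas.merge(pike_df[["site_id", "pike"]], left_on="area_id",
                             right_on="site_id").drop(columns=["site_id"])
    pred_cur = scenarios.predict_scenario(best_fit, areas_pike)
    pred_zero = scenarios.predict_scenario(best_fit, areas_pike, pike_override=0.0)
    deficits, totals = scenarios.compute_deficits(pred_zero, areas)
    headlines = scenarios.summarize_headlines(deficits, totals, pred_cur, areas)
    bench = deficits.merge(
        pred_cur[["area_id", "predicted_density"]].rename(
            columns={"predicted_density": "current_density"}), on="area_id")
    bench["benchmark_density"] = bench["benchmark_size"] / areas.set_index(
        "area_id").loc[bench["area_id"], "area_km2"].to_numpy()
    bench.to_csv(outdir / "benchmarks.csv", index=False)
    with open(outdir / "headlines.json", "w") as fh:
        json.dump(headlines, fh, indent=2, default=float)
    stages.append({"stage": "predict", "n_predictions": len(pred_cur),
                   "net_deficit": totals.net_deficit})

    # stage 6: nested Monte Carlo
    mc = uncertainty.propagate(best_fit, training, pike_df, areas_pike,
                               n_outer=config.n_outer, n_inner=config.n_inner,
                               seed=seeds[1])
    mc_summary = mc.summary()
    mc_summary.to_csv(outdir / "mc_summary.csv", index=False)
    stages.append({"stage": "propagate", "n_outer": config.n_outer,
                   "n_inner": config.n_inner,
                   "n_failed_refits": mc.n_failed_refits})

    # stage 7: report
    report_obj = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "stages": stages,
        "headlines": headlines,
    }
    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report_obj, fh, indent=2, default=float)
    stages.append({"stage": "report"})

    return {"areas": areas, "counts": counts, "carcasses": carcasses,
            "truth": study.get("truth"), "selection_report": report,
            "stable": stable, "pike": pike_df, "pike_glm": pike_glm,
            "training": training, "gam_selection": sel_table,
            "gam_fits": fits, "best_fit": best_fit,
            "predictions_current": pred_cur, "predictions_zero": pred_zero,
            "deficits": deficits, "totals": totals, "headlines": headlines,
            "mc": mc, "mc_summary": mc_summary, "report": report_obj}
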