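"""Replicate experiments that check the pipeline against generator truth.

These are the package's self-contained validation studies: stable-density
recovery from null-generated count series, pointwise recovery of the
stable-density surface by the GAM, PIKE-GLM coefficient recovery, and
prediction-interval coverage of the nested Monte Carlo. They are used by
both the test suite and the acceptance script, at replicate counts the
caller chooses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import gam, growth, pike, simulate, uncertainty


def stable_density_recovery(
    n_replicates: int = 200,
    survey_cv: float = 0.10,
    n_counts: int = 8,
    true_density: float = 1.5,
    area_km2: float = 5000.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Selection and bias of the null-model stable density on null series.

    Each replicate simulates one null-generated series and runs model
    selection; when the null wins, the extracted stable density (the fitted
    K) is compared with the generating density. Returns one row per
    replicate with the selected model and the relative bias.
    """
    ss = np.random.SeedSequence(seed).spawn(n_replicates)
    area = {"area_id": "SIM", "area_km2": area_km2}
    rows = []
    for child in ss:
        series = simulate.generate_time_series(
            area, "null", {"K": true_density}, n_counts, survey_cv, child)
        sel = growth.select_best_model(series)
        K = sel.fits["null"].params["K"]
        rows.append({"best_model": sel.best_model_id,
                     "rel_bias": K / true_density - 1.0})
    return pd.DataFrame(rows)


def surface_recovery_band(
    n_replicates: int = 200,
    n_train: int = 18,
    seed: int = 0,
    spec: simulate.SimulationSpec | None = None,
) -> pd.DataFrame:
    """Pointwise 95% simulation band of GAM-fitted densities around truth.

    Covariates are held fixed across replicates; each replicate redraws the
    negative-binomial training noise and refits the full-formula GAM. For
    each training point the 2.5-97.5 percentile band of fitted densities is
    compared with the generating density. Returns one row per point with
    the band and an in-band flag.
    """
    base = spec or simulate.SimulationSpec(seed=seed)
    spec0 = simulate.SimulationSpec(**{**base.__dict__, "n_areas": n_train,
                                       "seed": seed})
    areas = simulate.generate_protected_areas(spec0)
    fitted = np.empty((n_replicates, n_train))
    truth = None
    lam = None
    for i in range(n_replicates):
        spec_i = simulate.SimulationSpec(**{**base.__dict__, "seed": seed + 1 + i})
        tr, _ = simulate.generate_stable_density_training(spec_i, areas=areas)
        fit = gam.fit_gam(tr, "evi_water_pike", lambda0=lam,
                          gcv_maxiter=60, theta_iter=2)
        lam = fit.lambdas
        fitted[i] = fit.fitted / tr["area_km2"].to_numpy()
        if truth is None:
            truth = tr["true_density"].to_numpy()
    lo, hi = np.percentile(fitted, [2.5, 97.5], axis=0)
    return pd.DataFrame({"true_density": truth, "lo": lo, "hi": hi,
                         "in_band": (truth >= lo) & (truth <= hi)})


def pike_coefficient_recovery(
    n_replicates: int = 200,
    n_sites: int = 40,
    total_per_site: int = 80,
    intercept: float = -0.8,
    slope: float = 2.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Coverage of quasi-binomial Wald intervals for a logit-linear PIKE.

    Each replicate simulates sites with true PIKE = inv-logit(intercept +
    slope * x), fits the single-covariate candidate and records whether the
    95% Wald interval covers each true coefficient.
    """
    from scipy.special import expit
    rows = []
    for i in range(n_replicates):
        rng = np.random.default_rng(np.random.SeedSequence((seed, i)))
        x = rng.uniform(0.0, 1.0, n_sites)
        p = expit(intercept + slope * x)
        totals = np.full(n_sites, total_per_site)
        illegal = rng.binomial(totals, p)
        sites = pd.DataFrame({"site_id": [f"S{j}" for j in range(n_sites)],
                              "illegal_carcasses": illegal,
                              "total_carcasses": totals, "x": x})
        glm = pike.fit_pike_glm(sites, candidate_sets=[["x"]], covariates=["x"])
        res = glm.candidates[0]["fit"]
        ci = np.asarray(res.conf_int())
        est = res.params.to_numpy()
        truthv = np.array([intercept, slope])
        cover = (ci[:, 0] <= truthv) & (truthv <= ci[:, 1])
        rows.append({"b0": est[0], "b1": est[1],
                     "cover_b0": bool(cover[0]), "cover_b1": bool(cover[1])})
    return pd.DataFrame(rows)


def pi_coverage_experiment(
    n_replicates: int = 100,
    n_outer: int = 100,
    n_inner: int = 100,
    n_train: int = 18,
    n_predict: int = 30,
    se_frac: float = 0.10,
    noise: str = "normal",
    seed: int = 0,
) -> pd.DataFrame:
    """Coverage of nested-MC 95% prediction intervals for true stable sizes.

    Each replicate simulates a training set under the error law the pipeline
    itself assumes for extracted stable densities — truth plus zero-truncated
    normal error with a known SE, as produced by the time-series extraction
    stage — plus a separate prediction set from the same surface, fits the
    full-formula GAM, runs the nested propagation with all PIKE treated as
    empirical (the PIKE-GLM stage has its own recovery check), and records
    whether each prediction area's 95% PI for the current-conditions stable
    size covers the surface truth. Returns one row per (replicate, area).

    noise="nb" instead trains on negative-binomial ecological scatter
    (dispersion from the SimulationSpec) around the surface; see the methods
    note for
    how the two regimes bracket the calibration of the nested Monte Carlo.
    """
    rows = []
    for i in range(n_replicates):
        rep_seed = int(np.random.SeedSequence((seed, i)).generate_state(1)[0] % (2**31))
        spec = simulate.SimulationSpec(seed=rep_seed)
        spec_tr = simulate.SimulationSpec(**{**spec.__dict__, "n_areas": n_train,
                                             "seed": rep_seed})
        tr_areas = simulate.generate_protected_areas(spec_tr)
        tr_areas["area_id"] = [f"TR{j:03d}" for j in range(len(tr_areas))]
        tr, surface = simulate.generate_stable_density_training(
            spec, areas=tr_areas, se_frac=se_frac, noise=noise)
        tr["stable_density"] = tr["stable_size"] / tr["area_km2"]
        tr["stable_density_se"] = tr["stable_size_se"] / tr["area_km2"]

        spec_pr = simulate.SimulationSpec(**{**spec.__dict__, "n_areas": n_predict,
                                             "seed": rep_seed + 1})
        pr = simulate.generate_protected_areas(spec_pr)
        pr["area_id"] = [f"PR{j:03d}" for j in range(len(pr))]
        pr["pike"] = pr["true_pike"]
        pr["recent_estimate"] = 0.0
        true_size = np.asarray(surface(pr["evi"], pr["prop_12_water"],
                                       pr["true_pike"])) * pr["area_km2"].to_numpy()

        pike_table = pd.DataFrame({
            "site_id": np.concatenate([tr["area_id"], pr["area_id"]]),
            "pike": np.concatenate([tr["pike"], pr["pike"]]),
            "eta": 0.0, "eta_se": 0.0, "source": "empirical"})

        fit = gam.fit_gam(tr, "evi_water_pike")
        mc = uncertainty.propagate(fit, tr, pike_table, pr,
                                   n_outer=n_outer, n_inner=n_inner,
                                   seed=rep_seed + 2)
        lo, hi = np.percentile(mc.sizes_current, [2.5, 97.5], axis=0)
        for j in range(n_predict):
            rows.append({"replicate": i, "area": pr["area_id"].iloc[j],
                         "true_size": true_size[j],
                         "lo": lo[j], "hi": hi[j],
                         "covered": bool(lo[j] <= true_size[j] <= hi[j])})
    return pd.DataFrame(rows)
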