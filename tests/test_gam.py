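"""Negative-binomial GAM: closed forms, metrics, diagnostics, mgcv oracle."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import elebench as eb
from elebench.gam import (diagnostics, fit_gam, loocv_metrics,
                          mean_bias_error, select_gam, sensitivity_refit,
                          willmott_d)


class TestNullModel:
    def test_constant_density_and_poisson_limit(self, training18):
        """Null fit is a single density; in the Poisson limit it equals the
        aggregate density total stable size / total area exactly."""
        tr, _ = training18
        fit = fit_gam(tr, "null")
        dens = fit.fitted / tr["area_km2"].to_numpy()
        assert np.allclose(dens, dens[0], rtol=1e-10)   # constant density
        assert fit.deviance_explained == pytest.approx(0.0, abs=1e-8)
        agg = np.round(tr["stable_size"]).sum() / tr["area_km2"].sum()
        assert dens[0] == pytest.approx(agg, rel=0.25)  # NB-weighted mean
        fit_p = fit_gam(tr, "null", theta=1e8)          # Poisson limit
        dens_p = fit_p.fitted / tr["area_km2"].to_numpy()
        assert dens_p[0] == pytest.approx(agg, rel=1e-4)


class TestOffsetContract:
    def test_doubling_area_doubles_size(self, training18):
        tr, _ = training18
        fit = fit_gam(tr, "evi_water_pike")
        data = tr.copy()
        la1 = np.log(data["area_km2"].to_numpy())
        la2 = np.log(2.0 * data["area_km2"].to_numpy())
        s1 = fit.predict_size(data, la1)
        s2 = fit.predict_size(data, la2)
        assert np.allclose(s2, 2.0 * s1, rtol=1e-12)
        # densities unchanged
        assert np.allclose(s2 / (2 * data["area_km2"]), s1 / data["area_km2"],
                           rtol=1e-12)


class TestDevianceMonotonicity:
    @pytest.mark.parametrize("seed", [100, 101, 102, 103])
    def test_nested_candidates(self, seed):
        tr, _ = eb.generate_stable_density_training(eb.SimulationSpec(seed=seed))
        de = {fid: fit_gam(tr, fid).deviance_explained
              for fid in ("null", "evi_water", "evi_water_pike")}
        assert de["evi_water_pike"] >= de["evi_water"] - 1e-6
        assert de["evi_water"] >= de["null"] - 1e-6


class TestMetrics:
    def test_willmott_hand_value(self):
        # obs (1,2,3), pred (2,2,2): num = 2, denom = (|0|+|1|)^2+(0)+(0+1)^2 = 2
        assert willmott_d([1, 2, 3], [2, 2, 2]) == pytest.approx(0.0)

    def test_perfect_agreement(self):
        obs = np.array([1.0, 2.0, 5.0])
        assert willmott_d(obs, obs) == pytest.approx(1.0)
        assert mean_bias_error(obs, obs) == pytest.approx(0.0)

    def test_constant_prediction_bias(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = np.full(3, 2.5)
        assert mean_bias_error(obs, pred) == pytest.approx(0.5)

    def test_willmott_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            obs = rng.normal(size=8)
            pred = rng.normal(size=8)
            assert 0.0 <= willmott_d(obs, pred) <= 1.0

    def test_loocv_runs_and_is_finite(self, training18):
        tr, _ = training18
        cvcor, d, mbe = loocv_metrics(tr, "evi_water")
        assert -1.0 <= cvcor <= 1.0
        assert 0.0 <= d <= 1.0
        assert np.isfinite(mbe)


class TestSelection:
    def test_weights_sum_to_one(self, training18):
        tr, _ = training18
        table, fits = select_gam(tr)
        assert table["weight"].sum() == pytest.approx(1.0)
        assert table["selected"].sum() == 1
        sel = table.loc[table["selected"], "aicc"].iloc[0]
        assert sel == table.loc[table["admissible"], "aicc"].min()

    def test_pike_effect_detected_with_clear_signal(self, training60):
        """With low noise and a real poaching effect, the full model wins."""
        tr, _ = training60
        table, _ = select_gam(tr)
        assert table.loc[table["selected"], "formula_id"].iloc[0] == \
            "evi_water_pike"


class TestDiagnostics:
    def test_hat_properties(self, training18):
        tr, _ = training18
        fit = fit_gam(tr, "evi_water_pike")
        diag = diagnostics(fit)
        assert np.all(diag.hat >= 0) and np.all(diag.hat <= 1)
        assert diag.hat.sum() == pytest.approx(fit.edf, rel=1e-6)

    def test_balanced_duplicated_design_equal_hats(self):
        """Symmetric replicated designs spread leverage evenly."""
        base = pd.DataFrame({
            "area_id": list("abcd"),
            "evi": [0.1, 0.2, 0.3, 0.4],
            "prop_12_water": [0.2, 0.5, 0.8, 0.4],
            "pike": [0.1, 0.3, 0.2, 0.4],
            "area_km2": [2000.0] * 4,
        })
        data = pd.concat([base] * 4, ignore_index=True)
        data["log_area"] = np.log(data["area_km2"])
        data["stable_size"] = np.tile([900.0, 2200.0, 4100.0, 2500.0], 4)
        fit = fit_gam(data, "evi_water_pike", theta=5.0)
        h = fit.hat.reshape(4, 4)
        for col in range(4):
            assert np.allclose(h[:, col], h[0, col], atol=1e-8)

    def test_case_deletion_direction(self, training18):
        """Deleting the max-Cook row moves the fit more than a low-Cook row."""
        tr, _ = training18
        fit = fit_gam(tr, "evi_water_pike")
        diag = diagnostics(fit)
        hi = int(np.argmax(diag.cook))
        lo = int(np.argmin(diag.cook))
        la = tr["log_area"].to_numpy()
        out_hi = sensitivity_refit(tr, tr.index[hi], "evi_water_pike",
                                   predict_on=tr)
        out_lo = sensitivity_refit(tr, tr.index[lo], "evi_water_pike",
                                   predict_on=tr)
        shift_hi = np.mean(np.abs(out_hi["pred_full"] - out_hi["pred_reduced"])
                           / out_hi["pred_full"])
        shift_lo = np.mean(np.abs(out_lo["pred_full"] - out_lo["pred_reduced"])
                           / out_lo["pred_full"])
        assert shift_hi > shift_lo


class TestSensitivity:
    def test_dropping_duplicate_row_changes_nothing(self):
        rng = np.random.default_rng(17)
        base = pd.DataFrame({
            "area_id": [f"a{i}" for i in range(9)],
            "evi": rng.uniform(0.05, 0.4, 9),
            "prop_12_water": rng.uniform(0.2, 0.9, 9),
            "pike": rng.uniform(0.05, 0.5, 9),
            "area_km2": np.full(9, 3000.0),
        })
        base["log_area"] = np.log(base["area_km2"])
        base["stable_size"] = 3000.0 * np.exp(
            -1.0 + 3.0 * base["evi"] + base["prop_12_water"] - 2 * base["pike"])
        dup = pd.concat([base, base.iloc[[4]]], ignore_index=True)
        out = sensitivity_refit(dup, 9, "evi_water_pike", predict_on=base,
                                theta=50.0)
        assert out["correlation"] > 0.999
        assert np.allclose(out["pred_full"], out["pred_reduced"], rtol=0.02)


class TestAgainstMgcv:
    def test_fitted_values_match_reference(self, training18, tmp_path):
        """Independent reference fit (mgcv, rank-3 TPRS, NB, offset)."""
        tr, _ = training18
        d = tr[["evi", "prop_12_water", "pike", "log_area"]].copy()
        d["y"] = np.round(tr["stable_size"])
        csv = tmp_path / "train.csv"
        d.to_csv(csv, index=False)
        out = tmp_path / "fitted.csv"
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            library(mgcv)
            d <- read.csv("{csv}")
            m <- gam(y ~ s(evi, k=3) + s(prop_12_water, k=3) + s(pike, k=3)
                     + offset(log_area), family = nb(), data = d,
                     method = "REML")
            write.csv(data.frame(fitted = fitted(m),
                                 theta = m$family$getTheta(TRUE)),
                      "{out}", row.names = FALSE)
        """))
        res = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, timeout=300)
        assert res.returncode == 0, res.stderr
        ref = pd.read_csv(out)
        fit = fit_gam(tr, "evi_water_pike")
        corr = np.corrcoef(fit.fitted, ref["fitted"])[0, 1]
        assert corr > 0.97
        assert np.median(np.abs(fit.fitted / ref["fitted"] - 1.0)) < 0.15
        assert 0.4 < fit.theta / ref["theta"].iloc[0] < 2.5
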