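"""Growth-model curves, AICc selection and stable-density extraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import elebench as eb
from elebench.growth import MODEL_IDS, aicc, assess_robustness


class TestEvaluateModel:
    def test_logistic_closed_form(self):
        # K/(1 + ((K-N0)/N0) e^{-rt}) at K=2, N0=0.2, r=0.5, t=4
        expected = 2.0 / (1.0 + (1.8 / 0.2) * math.exp(-2.0))
        got = eb.evaluate_model("logistic", {"K": 2, "N0": 0.2, "r": 0.5},
                                np.array([4.0]))
        assert got[0] == pytest.approx(expected, rel=1e-12)

    def test_logistic_asymptote(self):
        got = eb.evaluate_model("logistic", {"K": 2, "N0": 0.2, "r": 0.5},
                                np.array([1e4]))
        assert got[0] == pytest.approx(2.0, rel=1e-9)

    def test_gompertz_fixed_point(self):
        t = np.linspace(0, 50, 11)
        got = eb.evaluate_model("gompertz", {"K": 3.0, "N0": 3.0, "r": 0.4}, t)
        assert np.allclose(got, 3.0)

    @pytest.mark.parametrize("model_id", ["exponential", "logistic", "gompertz"])
    def test_nonpositive_n0_rejected(self, model_id):
        params = {"K": 2.0, "N0": 0.0, "r": 0.1}
        with pytest.raises(ValueError):
            eb.evaluate_model(model_id, params, np.array([1.0]))


class TestAicc:
    def test_hand_value(self):
        expected = 10 * math.log(0.1) + 4 + 12 / 7
        assert aicc(rss=1.0, n=10, k=2) == pytest.approx(expected, rel=1e-12)

    def test_perfect_fit_dominates(self):
        assert aicc(0.0, 10, 4) == -math.inf

    def test_inadmissible_when_n_too_small(self):
        assert aicc(1.0, 5, 4) == math.inf

    @given(rss1=st.floats(0.01, 100), factor=st.floats(1.01, 10),
           n=st.integers(7, 50), k=st.integers(2, 4))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_rss(self, rss1, factor, n, k):
        assert aicc(rss1, n, k) < aicc(rss1 * factor, n, k)

    @given(rss=st.floats(0.01, 100), n=st.integers(7, 50))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_k(self, rss, n):
        assert aicc(rss, n, 2) < aicc(rss, n, 3) < aicc(rss, n, 4)


class TestEligibility:
    def test_below_min_counts_excluded(self, series_factory):
        s = series_factory([1.0, 1.1, 0.9, 1.0])  # 4 counts
        assert eb.filter_eligible_series([s]) == []

    def test_low_reliability_excluded(self, series_factory):
        s = series_factory([1.0] * 6, reliability="C")
        assert eb.filter_eligible_series([s]) == []

    def test_small_population_excluded(self, series_factory):
        s = series_factory([0.1] * 6, area_km2=1000.0)  # 100 elephants
        assert eb.filter_eligible_series([s]) == []

    def test_passing_series_retained_and_old_counts_dropped(self, series_factory):
        s = series_factory([1.0] * 11, start_year=1985)  # 1985-1995
        out = eb.filter_eligible_series([s])
        assert len(out) == 1
        assert out[0].years.min() >= 1989
        assert out[0].n == 7  # 1989..1995


class TestFitting:
    def test_null_exact(self, series_factory):
        s = series_factory([1.5] * 6)
        fit = eb.fit_model(s, "null")
        assert fit.params["K"] == pytest.approx(1.5, abs=1e-12)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_linear_exact_recovery(self, series_factory):
        t = np.arange(8.0)
        s = series_factory(1.0 + 0.05 * t)
        fit = eb.fit_model(s, "linear")
        assert fit.params["a"] == pytest.approx(1.0, abs=1e-9)
        assert fit.params["b"] == pytest.approx(0.05, abs=1e-9)

    @pytest.mark.parametrize("model_id,params", [
        ("exponential", {"N0": 0.5, "r": 0.08}),
        ("logistic", {"K": 2.0, "N0": 0.2, "r": 0.5}),
        ("gompertz", {"K": 2.0, "N0": 0.2, "r": 0.4}),
    ])
    def test_noiseless_nonlinear_recovery(self, series_factory, model_id, params):
        t = np.arange(10.0)
        s = series_factory(eb.evaluate_model(model_id, params, t))
        fit = eb.fit_model(s, model_id)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        for name, val in params.items():
            assert fit.params[name] == pytest.approx(val, rel=1e-3)

    def test_exponential_rate_recovery_distribution(self):
        """Fitted r over noisy replicates brackets the generating rate."""
        true_r = 0.06
        area = {"area_id": "A", "area_km2": 2000.0}
        rs = []
        for i in range(100):
            s = eb.generate_time_series(area, "exponential",
                                        {"N0": 0.8, "r": true_r}, 10, 0.08,
                                        seed=i)
            rs.append(eb.fit_model(s, "exponential").params["r"])
        lo, hi = np.percentile(rs, [2.5, 97.5])
        assert lo <= true_r <= hi
        assert np.median(rs) == pytest.approx(true_r, abs=0.02)


class TestSelection:
    @pytest.mark.parametrize("model_id,params", [
        ("null", {"K": 1.5}),
        ("linear", {"a": 1.0, "b": 0.05}),
        ("exponential", {"N0": 0.5, "r": 0.08}),
        ("logistic", {"K": 2.0, "N0": 0.2, "r": 0.5}),
        ("gompertz", {"K": 2.0, "N0": 0.2, "r": 0.4}),
    ])
    def test_noiseless_selection(self, series_factory, model_id, params):
        t = np.arange(10.0)
        s = series_factory(eb.evaluate_model(model_id, params, t))
        sel = eb.select_best_model(s)
        assert sel.best_model_id == model_id

    def test_tie_breaks_to_parsimony(self, series_factory):
        # constant series: every model can reach rss ~ 0; null (fewest params) wins
        s = series_factory([2.0] * 10)
        assert eb.select_best_model(s).best_model_id == "null"

    def test_time_origin_shift_invariance(self, series_factory):
        rng = np.random.default_rng(5)
        d = 1.5 + rng.normal(0, 0.1, 8)
        s1 = series_factory(d, start_year=1990)
        s2 = series_factory(d, start_year=2005)
        sel1, sel2 = eb.select_best_model(s1), eb.select_best_model(s2)
        assert sel1.best_model_id == sel2.best_model_id
        for m in ("null", "linear", "exponential"):
            assert sel1.fits[m].aicc == pytest.approx(sel2.fits[m].aicc,
                                                      rel=1e-6)


class TestLinearTrend:
    def test_constant_series(self, series_factory):
        assert eb.test_linear_trend(series_factory([1.0] * 6)) == pytest.approx(1.0)

    def test_strong_trend(self, series_factory):
        t = np.arange(10.0)
        p = eb.test_linear_trend(series_factory(1.0 + 0.5 * t))
        assert p < 1e-6

    def test_type_i_error_rate(self):
        """Null-generated series reject at roughly the nominal 5% level."""
        area = {"area_id": "A", "area_km2": 1000.0}
        rejections = 0
        n = 400
        for i in range(n):
            s = eb.generate_time_series(area, "null", {"K": 1.5}, 8, 0.1, seed=i)
            if eb.test_linear_trend(s) < 0.05:
                rejections += 1
        # 99.7% binomial envelope around 0.05 at n=400
        assert 0.017 <= rejections / n <= 0.083


class TestRobustness:
    def test_degenerate_mc_with_zero_ses(self, series_factory):
        rng = np.random.default_rng(3)
        s = series_factory(1.5 + rng.normal(0, 0.05, 8))
        rob, dens, se = assess_robustness(s, n_sims=50, seed=1)
        assert rob == 1.0
        assert dens == pytest.approx(np.mean(s.densities))
        assert se == 0.0

    def test_stable_density_matches_oracle_spread(self):
        """SE of the extracted density tracks an independent re-simulation."""
        area = {"area_id": "A", "area_km2": 1000.0}
        s = eb.generate_time_series(area, "null", {"K": 1.5}, 8, 0.05, seed=9)
        rob, dens, se = assess_robustness(s, n_sims=400, seed=2)
        # oracle: distribution of the mean of independent truncnorm redraws
        rng = np.random.default_rng(123)
        from scipy import stats as sps
        a = (0 - s.estimates) / s.ses
        draws = sps.truncnorm.rvs(a, np.inf, loc=s.estimates, scale=s.ses,
                                  size=(4000, s.n), random_state=rng)
        oracle_se = np.std(draws.mean(axis=1) / s.area_km2, ddof=1)
        assert dens == pytest.approx(np.mean(s.densities), rel=0.02)
        assert se == pytest.approx(oracle_se, rel=0.15)
        assert 0.0 <= rob <= 1.0

    def test_extracted_density_is_series_mean(self, series_factory):
        rng = np.random.default_rng(8)
        s = series_factory(2.0 + rng.normal(0, 0.1, 8))
        sel = eb.select_best_model(s)
        assert sel.best_model_id == "null"
        assert sel.fits["null"].params["K"] == pytest.approx(
            np.mean(s.densities), abs=1e-12)


def test_extract_stable_densities_report(series_factory):
    rng = np.random.default_rng(11)
    series = [series_factory(1.5 + rng.normal(0, 0.08, 8),
                             ses=np.full(8, 50.0), area_id=f"A{i}")
              for i in range(3)]
    report, stable = eb.extract_stable_densities(series, n_sims=30, seed=4)
    assert len(report) == 3
    assert set(stable.columns) >= {"area_id", "density", "se", "n_sims"}
    assert (report["robustness"].between(0, 1)).all()
    for m in MODEL_IDS:
        assert f"aicc_{m}" in report.columns
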