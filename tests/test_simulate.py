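"""Synthetic-data generator: determinism, ranges, and noise laws."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import elebench as eb


class TestProtectedAreas:
    def test_same_seed_identical(self):
        spec = eb.SimulationSpec(seed=7)
        a = eb.generate_protected_areas(spec)
        b = eb.generate_protected_areas(spec)
        pd.testing.assert_frame_equal(a, b)

    def test_empty(self):
        assert len(eb.generate_protected_areas(eb.SimulationSpec(n_areas=0))) == 0

    def test_count_and_ranges(self):
        spec = eb.SimulationSpec(n_areas=73, seed=1)
        a = eb.generate_protected_areas(spec)
        assert len(a) == 73
        assert a["area_km2"].between(1020, 47666).all()
        assert a["evi"].between(0.05, 0.404).all()
        assert a["true_pike"].between(0, 1).all()

    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(1, 40))
    @settings(max_examples=25, deadline=None)
    def test_invariants_hold_for_any_seed(self, seed, n):
        spec = eb.SimulationSpec(n_areas=n, seed=seed)
        a = eb.generate_protected_areas(spec)
        assert (a["area_km2"] > 0).all()
        assert a["evi"].between(0, 1).all()
        assert a["prop_12_water"].between(0, 1).all()
        assert a["true_pike"].between(0, 1).all()

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            eb.SimulationSpec(evi_range=(0.5, 0.1))
        with pytest.raises(ValueError):
            eb.SimulationSpec(water_range=(0.0, 1.5))
        with pytest.raises(ValueError):
            eb.SimulationSpec(survey_cv=-0.1)
        with pytest.raises(ValueError):
            eb.SimulationSpec(nb_dispersion=0.0)


class TestTimeSeries:
    AREA = {"area_id": "A", "area_km2": 1000.0}

    def test_zero_noise_constant(self):
        ts = eb.generate_time_series(self.AREA, "null", {"K": 5.0}, 6, 0.0, seed=0)
        assert np.allclose(ts.estimates, 5000.0)
        assert np.allclose(ts.ses, 0.0)

    def test_logistic_mean_trajectory(self):
        """Simulated means converge on the closed-form logistic curve."""
        params = {"K": 2.0, "N0": 0.4, "r": 0.35}
        n_rep, n_counts = 400, 8
        acc = np.zeros(n_counts)
        for i in range(n_rep):
            ts = eb.generate_time_series(self.AREA, "logistic", params,
                                         n_counts, 0.1, seed=i)
            acc += ts.estimates
        mean = acc / n_rep
        t = np.arange(n_counts, dtype=float)
        expected = eb.evaluate_model("logistic", params, t) * 1000.0
        # truncation at 0 is negligible at cv = 0.1: means within ~3 MC SE
        mc_se = 0.1 * expected / np.sqrt(n_rep)
        assert np.all(np.abs(mean - expected) < 4 * mc_se)
        assert np.all(np.diff(expected) > 0)

    def test_empirical_cv_matches_generator(self):
        vals = []
        for i in range(1000):
            ts = eb.generate_time_series(self.AREA, "null", {"K": 1.5}, 2,
                                         0.1, seed=i)
            vals.append(ts.estimates[0])
        cv = np.std(vals) / np.mean(vals)
        assert cv == pytest.approx(0.1, abs=0.012)

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError):
            eb.generate_time_series(self.AREA, "null", {"K": 1.0}, 5, -0.1, seed=0)

    def test_total_count_mode_gives_zero_se(self):
        ts = eb.generate_time_series(self.AREA, "null", {"K": 2.0}, 20, 0.1,
                                     seed=3, total_count_prob=1.0)
        assert np.allclose(ts.ses, 0.0)
        assert np.allclose(ts.estimates, 2000.0)


class TestCarcasses:
    def test_pike_zero_boundary(self):
        df = eb.generate_carcass_records(["s1"] * 5, [0.0] * 5,
                                         [30] * 5, seed=0)
        assert (df["illegal_carcasses"] == 0).all()

    def test_pike_one_boundary(self):
        df = eb.generate_carcass_records(["s1"] * 5, [1.0] * 5,
                                         [30] * 5, seed=0)
        assert (df["illegal_carcasses"] == df["total_carcasses"]).all()

    def test_binomial_interval(self):
        df = eb.generate_carcass_records(["s"], [0.3], [1000], seed=5)
        phat = df["illegal_carcasses"].iloc[0] / 1000
        # 99% binomial envelope around 0.3 at n=1000
        assert abs(phat - 0.3) < 2.58 * np.sqrt(0.3 * 0.7 / 1000)

    def test_validation(self):
        with pytest.raises(ValueError):
            eb.generate_carcass_records(["s"], [1.2], [10], seed=0)
        with pytest.raises(ValueError):
            eb.generate_carcass_records(["s"], [0.5], [-1], seed=0)


class TestStableDensityTraining:
    def test_row_count(self):
        tr, _ = eb.generate_stable_density_training(eb.SimulationSpec(seed=0))
        assert len(tr) == 18
        assert (tr["stable_size_se"] > 0).all()

    def test_flat_surface_mean_density(self):
        surf = eb.DensitySurface(b0=np.log(1.2), b_evi=0, b_water=0, b_pike=0)
        spec = eb.SimulationSpec(seed=4, true_surface=surf, nb_dispersion=50.0)
        tr, _ = eb.generate_stable_density_training(spec, n_train=400)
        assert tr["stable_density"].mean() == pytest.approx(1.2, rel=0.05)

    def test_nb_variance_mean_relation(self):
        """Variance/mean ratio matches 1 + mu/theta; Poisson in the limit."""
        surf = eb.DensitySurface(b0=0.0, b_evi=0, b_water=0, b_pike=0)
        spec = eb.SimulationSpec(seed=6, true_surface=surf, nb_dispersion=3.1,
                                 area_range_km2=(100.0, 100.0))
        tr, _ = eb.generate_stable_density_training(spec, n_train=3000)
        mu = 100.0
        ratio = tr["stable_size"].var() / tr["stable_size"].mean()
        assert ratio == pytest.approx(1 + mu / 3.1, rel=0.15)

        spec_p = eb.SimulationSpec(seed=6, true_surface=surf,
                                   nb_dispersion=np.inf,
                                   area_range_km2=(100.0, 100.0))
        trp, _ = eb.generate_stable_density_training(spec_p, n_train=3000)
        ratio_p = trp["stable_size"].var() / trp["stable_size"].mean()
        assert ratio_p == pytest.approx(1.0, rel=0.15)

    def test_negative_surface_rejected(self):
        spec = eb.SimulationSpec(seed=0)
        spec.true_surface = lambda e, w, p: np.asarray(e) - 10.0
        with pytest.raises(ValueError):
            eb.generate_stable_density_training(spec)


class TestStudy:
    def test_determinism(self):
        s1 = eb.simulate_study(eb.SimulationSpec(seed=11, n_areas=30,
                                                 dynamics={"null": 5}))
        s2 = eb.simulate_study(eb.SimulationSpec(seed=11, n_areas=30,
                                                 dynamics={"null": 5}))
        for k in s1:
            pd.testing.assert_frame_equal(s1[k], s2[k])

    def test_schema_and_truth_alignment(self):
        spec = eb.SimulationSpec(seed=12, n_areas=30,
                                 dynamics={"null": 6, "exponential": 2})
        study = eb.simulate_study(spec)
        assert len(study["areas"]) == 30
        assert study["counts"]["area_id"].nunique() == 8
        null_ids = study["truth"].loc[study["truth"]["dynamics"] == "null",
                                      "area_id"]
        assert len(null_ids) == 6
        # null areas fluctuate around the current-conditions surface density
        merged = study["truth"].set_index("area_id")
        counts = study["counts"]
        for aid in null_ids:
            area = study["areas"].set_index("area_id").loc[aid, "area_km2"]
            d = counts.loc[counts["area_id"] == aid, "estimate"] / area
            assert d.mean() == pytest.approx(
                merged.loc[aid, "true_density_current"], rel=0.25)
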