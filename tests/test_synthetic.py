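"""Ground-truth generator: geography, exposure fields, mortality."""

import numpy as np
import pandas as pd
import pytest

from lagcrossover.exposure import build_locality_series
from lagcrossover.scenarios import moments_scenario
from lagcrossover.synthetic import (
    GroundTruth,
    SyntheticScenario,
    betas_for_lag06_percent,
    simulate_exposure_fields,
    simulate_geography,
    simulate_mortality,
    simulate_study,
)


class TestScenarioValidation:
    def test_beta_vector_must_have_seven_finite_values(self):
        with pytest.raises(ValueError, match="7 finite"):
            SyntheticScenario(true_lag_betas_pm=np.zeros(6))
        with pytest.raises(ValueError, match="7 finite"):
            SyntheticScenario(true_lag_betas_pm=[0, 0, 0, np.inf, 0, 0, 0])

    def test_ar1_inside_unit_interval(self):
        with pytest.raises(ValueError, match="AR"):
            SyntheticScenario(ar1_coef_pm=1.0)

    def test_cause_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticScenario(cause_mix={"I21": 0.5, "K70": 0.4})

    def test_baseline_rate_positive(self):
        with pytest.raises(ValueError, match="baseline"):
            SyntheticScenario(baseline_rate=0.0)


class TestGeography:
    def test_minimal_tiling_one_urban_four_cells(self):
        sc = SyntheticScenario(
            n_urban_localities=1, n_rural_localities=0, grid_shape=(2, 2)
        )
        grid, locs, pop = simulate_geography(sc)
        assert len(locs) == 1 and locs[0].urban
        cover = grid.intersecting_cells(locs[0].geometry)
        assert len(cover) == 4 and all(f == pytest.approx(1.0) for f in cover.values())
        assert all(pop[c] > 0 for c in cover)

    def test_study_scale_urban_rural_counts(self):
        sc = SyntheticScenario(
            n_urban_localities=255, n_rural_localities=412, grid_shape=(40, 40)
        )
        _, locs, _ = simulate_geography(sc)
        assert len(locs) == 667
        assert sum(l.urban for l in locs) == 255
        assert sum(not l.urban for l in locs) == 412

    def test_rural_points_fall_in_exactly_one_cell(self):
        sc = SyntheticScenario(n_urban_localities=2, n_rural_localities=6)
        grid, locs, _ = simulate_geography(sc)
        for l in locs:
            if not l.urban:
                grid.cell_of_point(l.geometry.x, l.geometry.y)  # must not raise

    def test_capacity_errors(self):
        with pytest.raises(ValueError, match="at most"):
            simulate_geography(
                SyntheticScenario(n_urban_localities=5, grid_shape=(2, 2))
            )
        with pytest.raises(ValueError, match="free cells"):
            simulate_geography(
                SyntheticScenario(
                    n_urban_localities=1, n_rural_localities=50, grid_shape=(2, 4)
                )
            )

    def test_same_seed_reproduces_geometry(self):
        sc = SyntheticScenario(seed=42)
        g1, l1, p1 = simulate_geography(sc)
        g2, l2, p2 = simulate_geography(sc)
        assert p1 == p2
        assert all(a.geometry.equals(b.geometry) for a, b in zip(l1, l2))


class TestExposureFields:
    def test_degenerate_parameters_give_constant_field(self):
        sc = SyntheticScenario(
            seasonal_amplitude_pm=0.0, ar1_coef_pm=0.0, spatial_sd_pm=0.0,
            noise_sd_pm=0.0, seasonal_amplitude_temp=0.0, spatial_sd_temp=0.0,
            noise_sd_temp=0.0, cross_corr=0.0,
            date_range=("2004-01-01", "2004-03-31"),
        )
        grid, _, _ = simulate_geography(sc)
        f = simulate_exposure_fields(sc, grid)
        assert np.allclose(f.pm, sc.mean_pm)
        assert np.allclose(f.temp, sc.mean_temp)

    def test_marginal_moments_near_targets(self):
        sc = moments_scenario(seed=5)
        grid, _, _ = simulate_geography(sc)
        f = simulate_exposure_fields(sc, grid)
        assert f.pm.mean() == pytest.approx(24.6, abs=0.5)
        assert f.pm.std() == pytest.approx(10.8, abs=0.5)
        assert f.pm.min() >= 0.0
        assert f.temp.mean() == pytest.approx(16.6, abs=0.5)

    def test_lag1_autocorrelation_matches_generating_coefficient(self):
        sc = SyntheticScenario(
            seasonal_amplitude_pm=0.0, spatial_sd_pm=0.0, ar1_coef_pm=0.6,
            date_range=("2004-01-01", "2012-12-31"),  # > 3000 days
        )
        grid, _, _ = simulate_geography(sc)
        f = simulate_exposure_fields(sc, grid)
        s = f.pm[:, 10]
        acf1 = np.corrcoef(s[1:], s[:-1])[0, 1]
        assert acf1 == pytest.approx(0.6, abs=0.05)

    def test_same_seed_reproduces_fields(self):
        sc = SyntheticScenario(seed=9, date_range=("2004-01-01", "2004-06-30"))
        grid, _, _ = simulate_geography(sc)
        f1 = simulate_exposure_fields(sc, grid)
        f2 = simulate_exposure_fields(sc, grid)
        np.testing.assert_array_equal(f1.pm, f2.pm)
        np.testing.assert_array_equal(f1.temp, f2.temp)

    def test_long_frame_round_trip(self):
        from lagcrossover.exposure import ExposureFields

        sc = SyntheticScenario(date_range=("2004-01-01", "2004-01-31"))
        grid, _, _ = simulate_geography(sc)
        f = simulate_exposure_fields(sc, grid)
        back = ExposureFields.from_frame(f.to_frame(), grid)
        np.testing.assert_allclose(back.pm, f.pm)


class TestMortality:
    def test_doubling_baseline_doubles_death_count(self):
        kw = dict(date_range=("2004-01-01", "2006-12-31"), baseline_rate=0.4, seed=2)
        n1 = len(simulate_study(SyntheticScenario(**kw)).records)
        kw["baseline_rate"] = 0.8
        n2 = len(simulate_study(SyntheticScenario(**kw)).records)
        assert n2 / n1 == pytest.approx(2.0, rel=0.05)

    def test_record_schema_and_demographic_levels(self, small_study):
        r = small_study.records
        assert list(r.columns) == [
            "death_date", "locality_id", "icd10", "age_years",
            "sex", "education", "insurance", "job_category",
        ]
        assert r["age_years"].ge(18).all()
        assert set(r["sex"]) <= {"male", "female"}
        assert set(r["icd10"]) <= set(small_study.scenario.cause_mix)

    def test_same_seed_reproduces_records(self):
        sc = SyntheticScenario(seed=13, baseline_rate=0.2,
                               date_range=("2004-01-01", "2004-12-31"))
        s1, s2 = simulate_study(sc), simulate_study(sc)
        pd.testing.assert_frame_equal(s1.records, s2.records)

    def test_missing_exposure_skips_locality_day_and_logs(self):
        sc = SyntheticScenario(seed=3, baseline_rate=5.0,
                               date_range=("2004-01-01", "2004-03-31"))
        grid, locs, pop = simulate_geography(sc)
        fields = simulate_exposure_fields(sc, grid)
        fields.pm[40, :] = np.nan  # one fully missing day
        series = build_locality_series(fields, locs, pop)
        records, skipped = simulate_mortality(sc, series)
        # days 40..46 have incomplete lag histories for every locality
        bad = set(series.dates[40:47].date)
        assert bad <= set(pd.to_datetime(skipped["date"]).dt.date)
        assert not bad & set(records["death_date"].dt.date)

    def test_distinct_cause_gets_its_own_effect(self):
        own = betas_for_lag06_percent(8.0)
        sc = SyntheticScenario(
            seed=4, baseline_rate=0.5, distinct_cause=("I21", own),
            date_range=("2004-01-01", "2004-12-31"),
        )
        study = simulate_study(sc)
        assert (study.records["icd10"] == "I21").mean() == pytest.approx(
            sc.cause_mix["I21"], abs=0.05
        )


class TestGroundTruth:
    def test_percent_identity_recomputable_exactly(self):
        betas = betas_for_lag06_percent(2.0)
        gt = GroundTruth.from_betas(betas)
        assert gt.percent_per_10["lag06"] == pytest.approx(2.0, abs=1e-12)
        assert gt.cumulative_beta_lag06 == pytest.approx(betas.sum(), abs=0)
        assert gt.cumulative_beta_lag01 == pytest.approx(betas[:2].sum(), abs=0)
        recomputed = (np.exp(10 * gt.cumulative_beta_lag01) - 1) * 100
        assert gt.percent_per_10["lag01"] == recomputed
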