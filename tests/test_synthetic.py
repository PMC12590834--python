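from dataclasses import replace
from datetime import date

import numpy as np
import pandas as pd
import pytest

from sitefidelity.config import ConditionCoefs, GridSpec, SimulationConfig
from sitefidelity.fidelity import interannual_distance
from sitefidelity.foodscape import colwell_constancy, scale_stack
from sitefidelity.io import read_foodscape, read_neonates, read_telemetry, write_dataset
from sitefidelity.synthetic import (
    generate_foodscape,
    make_dataset,
    simulate_condition,
    simulate_reproduction,
    simulate_trajectories,
)

SMALL_GRID = GridSpec(0.0, 0.0, 250.0, 10, 10)


def small_config(**kw):
    base = dict(
        seed=11,
        n_animals=2,
        years=(2019, 2020),
        season_start=(6, 1),
        season_end=(6, 11),
        grid=SMALL_GRID,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestTrajectories:
    def test_default_fix_schedule_24_per_day(self):
        trs = simulate_trajectories(small_config())
        days = trs[0].fixes["timestamp"].dt.date
        assert (days.value_counts() == 24).all()

    def test_degenerate_parameters_pin_to_center(self):
        cfg = small_config(ou_diffusion=0.0, loc_error_sd_m=0.0, ou_center_shift_m=0.0)
        trs = simulate_trajectories(cfg)
        for tr in trs:
            assert np.ptp(tr.xy, axis=0).max() == 0.0
        # downstream fidelity distance is exactly zero
        by_year = {int(t.fixes["timestamp"].dt.year.iloc[0]): t for t in trs if t.animal_id == "F01"}
        rec = interannual_distance(by_year[2020], by_year[2019], 30)
        assert rec.distance_m == 0.0

    def test_ou_increment_variance_closed_form(self):
        cfg = small_config(seed=21, n_animals=5, season_end=(8, 31), loc_error_sd_m=0.0)
        trs = simulate_trajectories(cfg)
        incs = np.concatenate([np.diff(tr.xy, axis=0).ravel() for tr in trs])
        theta, D = cfg.ou_attraction, cfg.ou_diffusion
        sigma_st2 = D / (2 * theta)
        expect = 2.0 * sigma_st2 * (1.0 - np.exp(-theta))  # stationary 1-h displacement
        assert incs.size > 2 * 10_000
        assert np.var(incs) == pytest.approx(expect, rel=0.05)

    def test_center_shift_dials_interannual_distance(self):
        shifts = [0.0, 250.0, 1000.0, 4000.0]
        medians = []
        for shift in shifts:
            dists = []
            for seed in range(4):
                cfg = small_config(seed=40 + seed, n_animals=3, ou_center_shift_m=shift)
                trs = simulate_trajectories(cfg)
                by = {}
                for t in trs:
                    by.setdefault(t.animal_id, {})[int(t.fixes["timestamp"].dt.year.iloc[0])] = t
                for animal, yrs in by.items():
                    rec = interannual_distance(yrs[2020], yrs[2019], 366)
                    dists.append(rec.distance_m)
            medians.append(np.median(dists))
        from scipy.stats import spearmanr

        rho = spearmanr(shifts, medians).statistic
        assert rho > 0.9


class TestFoodscape:
    def test_persistent_field_identical_layers_constancy_one(self):
        cfg = small_config(field_temporal_ar=1.0, field_innovation_sd=0.0,
                           field_seasonal_amplitude=0.0)
        stack = generate_foodscape(cfg)
        assert np.allclose(stack.data, stack.data[0])
        scaled = scale_stack(stack)
        per_pixel = [
            colwell_constancy(scaled.data[:, r, c])
            for r in range(scaled.grid.nrows)
            for c in range(scaled.grid.ncols)
        ]
        assert np.mean(per_pixel) == pytest.approx(1.0)

    def test_one_layer_per_day_all_nonnegative(self):
        cfg = small_config()
        stack = generate_foodscape(cfg)
        assert len(stack.dates) == 20  # two 10-day seasons
        assert stack.data.min() >= 0.0

    def test_temporal_constancy_nonincreasing_in_innovation_sd(self):
        def mean_temporal_c(sd, seed):
            cfg = small_config(seed=seed, field_innovation_sd=sd, field_temporal_ar=0.5,
                               season_end=(7, 1), n_animals=1,
                               grid=GridSpec(0, 0, 250.0, 6, 6))
            scaled = scale_stack(generate_foodscape(cfg))
            return np.mean(
                [
                    colwell_constancy(scaled.data[:, r, c])
                    for r in range(6)
                    for c in range(6)
                ]
            )

        means = [
            np.mean([mean_temporal_c(sd, 60 + k) for k in range(10)])
            for sd in (0.0, 0.1, 0.5)
        ]
        assert means[0] >= means[1] - 1e-9 >= means[2] - 1e-9

    def test_spatial_constancy_nondecreasing_in_range(self):
        def mean_spatial_c(rng_m, seed):
            cfg = small_config(seed=seed, field_spatial_range_m=rng_m,
                               n_animals=1, grid=GridSpec(0, 0, 250.0, 6, 6))
            scaled = scale_stack(generate_foodscape(cfg))
            return np.mean([colwell_constancy(layer) for layer in scaled.data])

        means = [
            np.mean([mean_spatial_c(r, 80 + k) for k in range(10)])
            for r in (100.0, 1000.0, 100000.0)
        ]
        assert means[0] <= means[1] + 1e-9 <= means[2] + 1e-9

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            GridSpec(0, 0, 250.0, 0, 10)


class TestReproduction:
    def test_exponential_median_closed_form(self):
        cfg = SimulationConfig(
            seed=5, n_animals=500, years=(2019, 2020), hazard_rate_per_day=0.02,
            hazard_fidelity_beta=0.0, grid=SMALL_GRID,
        )
        recs = simulate_reproduction(cfg, trajectories=None)
        days = np.array([r.days_alive_known for r in recs], dtype=float)
        # censoring at 120 d barely affects the median at this rate
        assert len(recs) == 1000
        assert np.median(days) == pytest.approx(np.log(2) / 0.02, abs=2.5)

    def test_survivors_censored_at_120(self):
        recs = simulate_reproduction(small_config(), trajectories=None)
        for r in recs:
            if r.fate == "survived_window":
                assert r.days_alive_known == 120
            else:
                assert r.days_alive_known < 120

    def test_birth_dates_in_parturition_window(self):
        recs = simulate_reproduction(small_config(seed=9, n_animals=40), None)
        for r in recs:
            assert date(r.year, 5, 15) <= r.birth_date <= date(r.year, 6, 15)


class TestCondition:
    def _inputs(self, n=200, seed=3):
        rng = np.random.default_rng(seed)
        rec = pd.DataFrame(
            {
                "animal_id": [f"F{i:03d}" for i in range(n)],
                "year": 2020,
                "recruited": rng.uniform(size=n) < 0.5,
            }
        )
        fid = rec[["animal_id", "year"]].assign(distance_m=rng.lognormal(6, 1, n))
        return rec, fid

    def test_all_effects_zero_noise_zero_gives_intercept(self):
        coefs = ConditionCoefs(intercept=12.0, recruit_effect=0.0, fidelity_effect=0.0,
                               spring_fat_effect=0.0, residual_sd=0.0)
        cfg = small_config(condition_coefs=coefs)
        rec, fid = self._inputs()
        out = simulate_condition(cfg, rec, fid)
        assert np.allclose(out["autumn_fat_pct"], 12.0)

    def test_recruit_effect_recovered_by_ols(self):
        cfg = small_config(seed=13)
        rec, fid = self._inputs()
        out = simulate_condition(cfg, rec, fid)
        import statsmodels.api as sm

        X = sm.add_constant(
            pd.DataFrame(
                {
                    "recruit": rec["recruited"].astype(float),
                    "spring": out["spring_fat_pct"],
                }
            )
        )
        fit = sm.OLS(out["autumn_fat_pct"], X).fit()
        assert fit.params["recruit"] == pytest.approx(-3.0, abs=0.5)

    def test_rows_pair_spring_and_autumn_per_animal_year(self):
        cfg = small_config()
        rec, fid = self._inputs(n=20)
        out = simulate_condition(cfg, rec, fid)
        assert list(out.columns) == ["animal_id", "year", "spring_fat_pct", "autumn_fat_pct"]
        assert len(out) == 20
        assert not out[["spring_fat_pct", "autumn_fat_pct"]].isna().any().any()


class TestDatasetBundle:
    def test_same_seed_identical_outputs(self):
        a = make_dataset(small_config())
        b = make_dataset(small_config())
        for ta, tb in zip(a.trajectories, b.trajectories):
            pd.testing.assert_frame_equal(ta.fixes, tb.fixes)
        assert np.array_equal(a.foodscape.data, b.foodscape.data)
        assert a.neonates == b.neonates
        pd.testing.assert_frame_equal(a.condition, b.condition)

    def test_truth_contains_generating_parameters(self):
        ds = make_dataset(small_config())
        for key in ("seed", "ou_center_shift_m", "hazard_rate_per_day", "field_temporal_ar"):
            assert key in ds.truth
        assert ds.truth["seed"] == 11

    def test_round_trip_through_readers(self, tmp_path):
        ds = make_dataset(small_config())
        write_dataset(ds, tmp_path)
        trs = read_telemetry(tmp_path / "telemetry.csv")
        merged = {t.animal_id: t for t in trs}
        for tr in ds.trajectories:
            got = merged[tr.animal_id]
            sub = got.fixes[got.fixes["timestamp"].isin(tr.fixes["timestamp"])]
            assert np.allclose(sub[["x", "y"]].to_numpy(), tr.xy, atol=1e-3)
        stack = read_foodscape(tmp_path / "foodscape")
        assert stack.dates == ds.foodscape.dates
        assert np.allclose(stack.data, ds.foodscape.data, atol=1e-6)
        assert read_neonates(tmp_path / "neonates.csv") == list(ds.neonates)

    def test_foodscape_covers_every_trajectory_date(self):
        ds = make_dataset(small_config())
        dates = set(ds.foodscape.dates)
        for tr in ds.trajectories:
            assert set(tr.fixes["timestamp"].dt.date) <= dates
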