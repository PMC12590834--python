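import warnings
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from sitefidelity.inference import (
    CandidateModelSpec,
    LMMFit,
    NeonateSurvivalModel,
    aicc_model_average,
    assemble_table,
    candidate_sets,
    fit_condition_models,
    fit_lmm,
    mann_whitney_fidelity,
    screen_collinearity,
)
from sitefidelity.recruitment import NeonateRecord
from sitefidelity.synthetic import make_analysis_table


class TestCandidateSets:
    def test_heterogeneity_has_four_submodels(self):
        specs = [s for s in candidate_sets("annual") if s.set_name == "heterogeneity"]
        assert len(specs) == 4

    def test_combined_has_six_submodels(self):
        specs = [s for s in candidate_sets("annual") if s.set_name == "combined"]
        assert len(specs) == 6

    def test_single_previous_success_model(self):
        specs = [s for s in candidate_sets("annual") if s.set_name == "success"]
        assert len(specs) == 1

    def test_home_range_size_in_every_model(self):
        assert all("hr_area_km2" in s.terms for s in candidate_sets("annual"))

    def test_interactions_excluded_from_additive_inference(self):
        additive = candidate_sets("annual", include_interactions=False)
        assert all(":" not in t for s in additive for t in s.terms)
        assert len(additive) == 3 + 1 + 3


class TestCollinearityScreen:
    def _table(self, n=50, seed=0, copy_temporal=False):
        tab = make_analysis_table(n_rows=n, seed=seed)
        if copy_temporal:
            tab["temporal_C"] = tab["spatial_C"]  # r = 1
        return tab

    def test_independent_covariates_no_split(self):
        specs = candidate_sets("annual", include_interactions=False)
        out = screen_collinearity(self._table(), specs)
        assert {s.name for s in out} == {s.name for s in specs}

    def test_duplicated_covariate_splits_into_singletons(self):
        spec = CandidateModelSpec("het.predictability", ("spatial_C", "temporal_C"), "heterogeneity")
        out = screen_collinearity(self._table(copy_temporal=True), [spec])
        term_sets = {frozenset(s.terms) for s in out}
        assert term_sets == {frozenset({"spatial_C"}), frozenset({"temporal_C"})}

    def test_constant_covariate_removed_with_warning(self):
        tab = self._table()
        tab["mean_biomass"] = 1.0
        spec = CandidateModelSpec("het.quality", ("mean_biomass", "hr_area_km2"), "heterogeneity")
        with pytest.warns(UserWarning, match="constant"):
            out = screen_collinearity(tab, [spec])
        assert out[0].terms == ("hr_area_km2",)


class TestFitLMM:
    def test_zero_variance_random_effect_matches_ols(self):
        tab = make_analysis_table(n_rows=120, re_sd=0.0, seed=5)
        tab["group"] = [f"g{i}" for i in range(len(tab))]  # independent rows
        spec = CandidateModelSpec("m", ("spatial_C", "mean_biomass", "hr_area_km2"), "heterogeneity")
        fit = fit_lmm(spec, tab)
        X = sm.add_constant(tab[["spatial_C", "mean_biomass", "hr_area_km2"]])
        ols = sm.OLS(tab["log_distance"], X).fit()
        assert np.allclose(fit.params.to_numpy(), ols.params.to_numpy(), atol=1e-4)

    def test_known_effect_recovered_within_2se(self):
        tab = make_analysis_table(n_rows=300, seed=6)
        spec = CandidateModelSpec(
            "m", ("spatial_C", "temporal_C", "mean_biomass", "recruit", "hr_area_km2"),
            "combined",
        )
        fit = fit_lmm(spec, tab)
        assert abs(fit.params["spatial_C"] - 0.3) < 2 * fit.bse["spatial_C"]

    def test_too_few_rows_rejected(self):
        tab = make_analysis_table(n_rows=6, seed=7)
        spec = CandidateModelSpec(
            "m", ("spatial_C", "temporal_C", "mean_biomass", "recruit", "hr_area_km2"),
            "combined",
        )
        with pytest.raises(ValueError, match="rows"):
            fit_lmm(spec, tab)


def _fake_fit(name, llf, k=4, n=100, terms=("x",), beta=1.0, se=0.2):
    params = pd.Series({"Intercept": 0.0, **{t: beta for t in terms}})
    bse = pd.Series({"Intercept": 0.1, **{t: se for t in terms}})
    return LMMFit(
        spec=CandidateModelSpec(name, terms, "heterogeneity"),
        params=params, bse=bse, llf=llf, k=k, n=n, converged=True, singular=False,
    )


class TestModelAveraging:
    def test_single_model_weight_one(self):
        res = aicc_model_average([_fake_fit("only", -50.0, beta=0.7)])
        assert res.model_table["weight"].iloc[0] == pytest.approx(1.0)
        row = res.coefficients.set_index("term").loc["x"]
        assert row["beta"] == pytest.approx(0.7)

    def test_delta_two_closed_form_weights(self):
        # equal k -> delta AICc 2 <=> delta logLik 1
        fits = [_fake_fit("a", -50.0), _fake_fit("b", -51.0, terms=("y",))]
        res = aicc_model_average(fits)
        w = res.model_table.set_index("model")["weight"]
        assert w["a"] == pytest.approx(1 / (1 + np.exp(-1)), abs=1e-9)
        assert w["b"] == pytest.approx(np.exp(-1) / (1 + np.exp(-1)), abs=1e-9)

    def test_weights_sum_to_one(self):
        fits = [_fake_fit(f"m{i}", -50.0 - i, terms=(f"x{i}",)) for i in range(5)]
        res = aicc_model_average(fits)
        assert res.model_table["weight"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_confidence_set_minimal(self):
        fits = [_fake_fit(f"m{i}", -50.0 - 1.5 * i, terms=("x",)) for i in range(6)]
        res = aicc_model_average(fits)
        tab = res.model_table
        inset = tab[tab["in_confidence_set"]]
        assert inset["weight"].sum() >= 0.95
        assert inset["weight"].sum() - inset["weight"].iloc[-1] < 0.95

    def test_averaged_beta_is_convex_combination(self):
        tab = make_analysis_table(n_rows=200, seed=8)
        from sitefidelity.inference import FidelityModelSet

        res = FidelityModelSet(tab, "annual").fit()
        by_name = {f.spec.name: f for f in res.fits}
        for row in res.coefficients.itertuples():
            betas = [
                f.params[row.term]
                for f in res.fits
                if row.term in f.params.index
                and res.model_table.set_index("model").loc[f.spec.name, "in_confidence_set"]
            ]
            assert min(betas) - 1e-12 <= row.beta <= max(betas) + 1e-12

    def test_mixed_row_counts_rejected(self):
        with pytest.raises(ValueError, match="identical data rows"):
            aicc_model_average([_fake_fit("a", -50.0, n=100), _fake_fit("b", -50.0, n=90)])

    def test_summary_renders(self):
        res = aicc_model_average([_fake_fit("only", -50.0)])
        text = res.summary()
        assert "AICc" in text and "only" in text


class TestAssembleTable:
    def _keyed(self, keys, **cols):
        df = pd.DataFrame(keys, columns=["animal_id", "year", "index"])
        for c, v in cols.items():
            df[c] = v
        return df

    def test_disjoint_keys_empty_with_warning(self):
        fid = self._keyed([("F01", 2020, 1)], distance_m=100.0, matched_fraction=1.0)
        con = self._keyed([("F02", 2020, 1)], temporal_C=0.5, spatial_C=0.5, mean_biomass=0.5)
        rec = self._keyed([("F02", 2020, 1)], status="success")
        hr = self._keyed([("F02", 2020, 1)], hr_area_km2=3.0)
        with pytest.warns(UserWarning, match="empty"):
            out = assemble_table(fid, con, rec, hr, "annual")
        assert out.empty

    def test_row_counts_and_unknown_exclusion(self):
        keys = [("F01", 2020, 1), ("F02", 2020, 1), ("F03", 2020, 1)]
        fid = self._keyed(keys, distance_m=[100.0, 200.0, 300.0], matched_fraction=1.0)
        con = self._keyed(keys, temporal_C=[0.5, 0.6, 0.7], spatial_C=0.5, mean_biomass=0.5)
        rec = self._keyed(keys, status=["success", "unknown", "failure"])
        hr = self._keyed(keys, hr_area_km2=[3.0, 4.0, 5.0])
        with pytest.warns(UserWarning, match="unknown recruitment"):
            out = assemble_table(fid, con, rec, hr, "annual")
        assert len(out) == 2
        assert out["recruit"].tolist() == [1, 0]
        # standardized covariates are mean 0 within scale x site
        assert out["temporal_C"].mean() == pytest.approx(0.0, abs=1e-12)

    def test_duplicate_keys_error(self):
        keys = [("F01", 2020, 1), ("F01", 2020, 1)]
        fid = self._keyed(keys, distance_m=1.0, matched_fraction=1.0)
        with pytest.raises(ValueError, match="duplicate"):
            assemble_table(fid, fid, fid, fid, "annual")


class TestConditionModels:
    def _condition(self, n=200, seed=1, recruit_effect=-3.0):
        rng = np.random.default_rng(seed)
        recruit = rng.uniform(size=n) < 0.4
        spring = rng.normal(8, 2, n)
        dist = rng.lognormal(6, 0.8, n)
        autumn = 13.0 + recruit_effect * recruit + 0.3 * spring + rng.normal(0, 1.5, n)
        return pd.DataFrame(
            {
                "animal_id": [f"F{i % 50:02d}" for i in range(n)],
                "year": 2019 + (np.arange(n) // 50) % 4,
                "spring_fat_pct": spring,
                "autumn_fat_pct": autumn,
                "distance_m": dist,
                "recruited": recruit,
            }
        )

    def test_recruit_effect_recovered_within_2se(self):
        out = fit_condition_models(self._condition())
        coefs = out["autumn_fat_pct"].set_index("term")
        assert abs(coefs.loc["recruit", "beta"] - (-3.0)) < 2 * coefs.loc["recruit", "se"]

    def test_spring_fat_only_in_accrual_model(self):
        out = fit_condition_models(self._condition())
        assert "spring_fat_pct" not in out["autumn_fat_pct"]["term"].tolist()
        assert "spring_fat_pct" in out["fat_accrual"]["term"].tolist()

    def test_interaction_dropped_with_few_recruits(self):
        df = self._condition(n=60, seed=2)
        df["recruited"] = False
        df.loc[:1, "recruited"] = True  # 2 successful recruits < 3
        out = fit_condition_models(df)
        assert "fidelity_z:recruit" not in out["autumn_fat_pct"]["term"].tolist()

    def test_zero_effect_ci_covers_zero_in_most_runs(self):
        covered = 0
        for seed in range(10):
            out = fit_condition_models(self._condition(seed=100 + seed, recruit_effect=0.0))
            c = out["autumn_fat_pct"].set_index("term").loc["recruit"]
            covered += int(c["ci_low"] <= 0.0 <= c["ci_high"])
        assert covered >= 9


class TestSurvival:
    def _records(self, n=150, beta=0.0, rate=0.01, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for i in range(n):
            z = rng.standard_normal()
            t = rng.exponential(1.0 / (rate * np.exp(beta * z)))
            birth = date(2020, 5, 20)
            if t >= 120:
                recs.append(NeonateRecord(f"F{i % 75:02d}", 2020, birth,
                                          birth + timedelta(days=120), "survived_window", z))
            else:
                recs.append(NeonateRecord(f"F{i % 75:02d}", 2020, birth,
                                          birth + timedelta(days=int(t)), "died", z))
        return recs

    def test_null_effect_ci_covers_zero_at_nominal_rate(self):
        # any single draw misses with 5% probability; check coverage instead
        covered = 0
        for seed in range(20):
            cox = NeonateSurvivalModel(self._records(beta=0.0, seed=seed)).fit()
            covered += int(cox.ci_low <= 0.0 <= cox.ci_high)
            assert cox.hazard_ratio == pytest.approx(np.exp(cox.beta))
        assert covered >= 17

    def test_too_few_events_advises_rank_test(self):
        recs = self._records(n=40, rate=0.0002, seed=4)
        with pytest.raises(ValueError, match="mann_whitney"):
            NeonateSurvivalModel(recs).fit()

    def test_event_and_censor_counts(self):
        recs = self._records(seed=5)
        model = NeonateSurvivalModel(recs)
        cox = model.fit()
        assert cox.n == 150
        assert cox.n_events + cox.n_censored == 150
        assert cox.n_events == sum(r.fate == "died" for r in recs)


class TestMannWhitney:
    def test_separated_groups_exact_p(self):
        u, p = mann_whitney_fidelity([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 exact two-sided

    def test_identical_groups_maximal_p(self):
        u, p = mann_whitney_fidelity([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_fidelity([], [1.0])
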