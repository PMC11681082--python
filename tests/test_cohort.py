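"""Synthetic cohort generator: determinism, limits, and building blocks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

import huitraj as ht
from huitraj.cohort import ConfigurationError
from huitraj.design import evaluate_terms


class TestGenerateCohort:
    def test_seed_determinism(self):
        cfg = ht.CohortConfig(n_participants=300, seed=11)
        a = ht.generate_cohort(cfg)
        b = ht.generate_cohort(ht.CohortConfig(n_participants=300, seed=11))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = ht.generate_cohort(ht.CohortConfig(n_participants=100, seed=1))
        b = ht.generate_cohort(ht.CohortConfig(n_participants=100, seed=2))
        assert not a["hui"].equals(b["hui"])

    def test_noise_free_limit_reproduces_mean_trajectory(self, clean_config):
        cfg = clean_config(seed=3, n=200, attrition="none", residual_sd=0.0)
        cfg.random_effect_sd = {"intercept": 0.0, "age_slope": 0.0}
        panel = ht.generate_cohort(cfg)
        terms = list(cfg.true_fixed_effects)
        X = evaluate_terms(panel, terms, exposure_window="period_mean")
        eta = X.to_numpy() @ np.array([cfg.true_fixed_effects[t] for t in terms])
        np.testing.assert_allclose(panel["hui"].to_numpy(), eta, rtol=0, atol=1e-12)

    def test_age_increments_by_cycle_spacing(self):
        panel = ht.generate_cohort(ht.CohortConfig(n_participants=50, seed=5))
        diffs = panel.groupby("participant_id")["age"].diff().dropna()
        assert np.allclose(diffs, 2.0)

    def test_invalid_marginals_error_names_variable(self):
        cfg = ht.CohortConfig(n_participants=50, seed=0)
        cfg.covariate_marginals["sex"] = {"male": 0.7, "female": 0.7}
        with pytest.raises(ConfigurationError, match="sex"):
            ht.generate_cohort(cfg)

    def test_hui_missing_iff_not_observed(self):
        panel = ht.generate_cohort(ht.CohortConfig(n_participants=400, seed=9))
        observed = panel["alive"] & panel["responded"]
        assert panel.loc[observed, "hui"].notna().all()
        assert panel.loc[~observed, "hui"].isna().all()


class TestExposure:
    def test_no_variation_sources_constant_series(self):
        params = ht.ExposureParams(temporal_scale_sd=0.0, residence_sd=0.0,
                                   move_count_probs={1: 1.0},
                                   road_class_probs={"other": 1.0})
        e = ht.generate_exposure(200, params, seed=4)
        per_p = e.groupby("participant_id")["no2"].nunique()
        assert (per_p == 1).all()

    def test_invalid_sd_rejected(self):
        with pytest.raises(ConfigurationError, match="sd_ppb"):
            ht.generate_exposure(10, ht.ExposureParams(sd_ppb=0.0), seed=0)

    def test_positivity_floor(self):
        e = ht.generate_exposure(2000, seed=8)
        assert (e["no2"] >= ht.ExposureParams().background_ppb).all()

    def test_correlation_decreases_with_mobility_and_noise(self):
        from scipy.stats import spearmanr

        def rho(**kw):
            e = ht.generate_exposure(4000, ht.ExposureParams(**kw), seed=12)
            pm = e.groupby("participant_id")["no2"].mean()
            c1 = e[e["cycle"] == 1].set_index("participant_id")["no2"]
            return spearmanr(c1, pm).statistic

        base = rho()
        more_moves = rho(move_count_probs={1: 0.05, 2: 0.15, 3: 0.3, 4: 0.5})
        more_noise = rho(temporal_scale_sd=0.5)
        assert more_moves < base
        assert more_noise < base


class TestRoadGradient:
    @pytest.mark.parametrize("distance, road_class, expected", [
        (0.0, "highway", 1.65),
        (300.0, "highway", 1.0),
        (500.0, "highway", 1.0),
        (0.0, "major_road", 1.2),
        (100.0, "major_road", 1.0),
        (150.0, "highway", 1.325),   # linear decay midpoint
        (50.0, "other", 1.0),
    ])
    def test_examples(self, distance, road_class, expected):
        assert ht.road_gradient(distance, road_class) == pytest.approx(expected)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            ht.road_gradient(-1.0, "highway")

    @given(st.floats(min_value=0.0, max_value=1000.0),
           st.floats(min_value=0.0, max_value=1000.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_nonincreasing_and_bounded(self, d1, d2):
        lo, hi = sorted((d1, d2))
        for rc, factor in (("highway", 1.65), ("major_road", 1.2)):
            v_lo, v_hi = ht.road_gradient(lo, rc), ht.road_gradient(hi, rc)
            assert v_lo >= v_hi
            assert 1.0 <= v_hi <= v_lo <= factor


class TestHui:
    def test_constant_intercept_only(self):
        panel = ht.generate_cohort(ht.CohortConfig(n_participants=20, seed=2))
        hui = ht.generate_hui(panel, {"Intercept": 0.9}, None, 0.0, seed=0)
        assert (hui == 0.9).all()

    def test_linear_evaluation(self):
        panel = pd.DataFrame({"participant_id": [0, 1], "cycle": [1, 1],
                              "age": [40.0, 40.0], "no2": [10.0, 10.0]})
        hui = ht.generate_hui(panel, {"Intercept": 1.0, "age": -0.01},
                              None, 0.0, seed=0)
        assert np.allclose(hui, 0.6)

    def test_truncation_to_utility_range(self):
        panel = pd.DataFrame({"participant_id": [0, 1], "cycle": [1, 1],
                              "age": [40.0, 90.0], "no2": [10.0, 10.0]})
        hui = ht.generate_hui(panel, {"Intercept": 1.0, "age": -0.02},
                              None, 0.0, seed=0)
        assert hui.iloc[1] == pytest.approx(-0.36)
        assert hui.attrs["truncated_fraction"] == pytest.approx(0.5)

    def test_unresolvable_term_lists_known_names(self):
        panel = ht.generate_cohort(ht.CohortConfig(n_participants=20, seed=2))
        with pytest.raises(KeyError, match="known covariate names"):
            ht.generate_hui(panel, {"Intercept": 0.9, "banana": 1.0}, None, 0.0, 0)


class TestAttrition:
    def test_null_model_completion_matches_percycle_probability(self):
        cfg = ht.CohortConfig(n_participants=8000, seed=31)
        q = 0.9
        cfg.attrition_coefficients = {
            "survival": {"Intercept": 30.0},
            "response": {"Intercept": float(np.log(q / (1 - q)))},
        }
        panel = ht.generate_cohort(cfg)
        s = ht.completion_summary(panel)
        assert s["pct_died"] == 0.0
        assert s["pct_completed"] / 100 == pytest.approx(q ** 8, abs=0.02)

    def test_negative_no2_coefficient_lowers_top_quartile_completion(self):
        cfg = ht.CohortConfig(n_participants=8000, seed=32)
        cfg.attrition_coefficients = {
            "survival": {"Intercept": 30.0},
            "response": {"Intercept": 2.2, "no2_c": -0.08},
        }
        panel = ht.generate_cohort(cfg)
        table = ht.participant_table(panel)
        q1, q3 = table["no2_period_mean"].quantile([0.25, 0.75])
        top = table[table["no2_period_mean"] >= q3]["completed_all_cycles"].mean()
        bottom = table[table["no2_period_mean"] <= q1]["completed_all_cycles"].mean()
        assert top < bottom

    def test_death_is_absorbing_and_blocks_response(self):
        panel = ht.generate_cohort(ht.CohortConfig(n_participants=2000, seed=33))
        g = panel.sort_values("cycle").groupby("participant_id")
        alive_seq = g["alive"].apply(lambda s: s.astype(int).is_monotonic_decreasing)
        assert alive_seq.all()
        dead_resp = panel[~panel["alive"]]["responded"]
        assert not dead_resp.any()


class TestBootstrapWeights:
    def test_reproducible(self):
        a = ht.generate_bootstrap_weights(5, 3, seed=7)
        b = ht.generate_bootstrap_weights(5, 3, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_replicate_means_match_main_mean(self):
        w = ht.generate_bootstrap_weights(200, 20, seed=3,
                                          main_weights=np.random.default_rng(0).uniform(0.5, 2, 200))
        for c in w.columns:
            assert w[c].mean() == pytest.approx(w["weight"].mean())

    def test_positive_and_requires_two_replicates(self):
        w = ht.generate_bootstrap_weights(50, 10, seed=1)
        assert (w >= 0).all().all()
        with pytest.raises(ConfigurationError):
            ht.generate_bootstrap_weights(50, 1, seed=1)

    def test_replicate_variance_tracks_analytic_variance_of_mean(self):
        # weighted mean of iid data across replicates vs s^2/n
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 400)
        w = ht.generate_bootstrap_weights(400, 400, seed=6)
        reps = [np.average(x, weights=w[c]) for c in w.columns if c != "weight"]
        assert np.var(reps) == pytest.approx(x.var() / 400, rel=0.3)


class TestActivity:
    @pytest.mark.parametrize("energy, expected", [
        (3.0, "active"), (4.5, "active"),
        (1.5, "moderate"), (2.99, "moderate"),
        (0.0, "inactive"), (1.49, "inactive"),
    ])
    def test_index_cutpoints(self, energy, expected):
        assert ht.physical_activity_index(energy) == expected

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            ht.physical_activity_index(-0.1)

    @pytest.mark.parametrize("leisure, work, employed, expected", [
        ([2, 2, 2], [4, 4, 4], [True] * 3, 6.0),
        ([3], [], None, 3.0),
        ([1, 2, 3], [4, 5], None, 6.5),
        ([1, 1], [5, 5], [False, False], 1.0),
    ])
    def test_combined_score(self, leisure, work, employed, expected):
        assert ht.combined_activity_score(leisure, work, employed) == expected

    def test_all_missing_leisure_flagged(self):
        assert np.isnan(ht.combined_activity_score([np.nan], [2.0]))
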