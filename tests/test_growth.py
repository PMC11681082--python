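"""Growth-curve model: transform, design matrix, weighted ML fit, AIC
retention, bootstrap variance and quartile specification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import huitraj as ht
from huitraj.design import ModelSpec


class TestTransform:
    def test_fixed_points(self):
        assert ht.transform_hui(0.32) == pytest.approx(0.0, abs=1e-12)
        assert ht.transform_hui(1.0) == pytest.approx(np.pi / 2, abs=1e-6)
        assert ht.transform_hui(0.0) == pytest.approx(-0.4900, abs=5e-5)
        assert ht.transform_hui(-0.36) == pytest.approx(-np.pi / 2, abs=1e-6)

    @given(st.floats(min_value=-0.36, max_value=1.0))
    @settings(max_examples=100, deadline=None)
    def test_round_trip_identity(self, h):
        assert ht.inverse_transform_hui(ht.transform_hui(h)) == pytest.approx(h, abs=1e-12)

    @given(st.tuples(st.floats(-0.36, 1.0), st.floats(-0.36, 1.0)))
    @settings(max_examples=50, deadline=None)
    def test_monotone_increasing(self, pair):
        a, b = sorted(pair)
        assert ht.transform_hui(a) <= ht.transform_hui(b)
        if b - a > 1e-9:  # strict once the gap is resolvable in floats
            assert ht.transform_hui(a) < ht.transform_hui(b)

    def test_domain_error_names_position(self):
        with pytest.raises(ValueError, match="positions"):
            ht.transform_hui([0.5, 1.2])


class TestDesignMatrix:
    def _panel(self, **cols):
        base = {"participant_id": [0], "cycle": [1], "age": [10.0], "no2": [2.0]}
        base.update(cols)
        return pd.DataFrame(base)

    def test_base_model_has_four_columns(self):
        X, terms = ht.build_design_matrix(self._panel(),
                                          ModelSpec(exposure_form="none"))
        assert terms == ["Intercept", "age", "age^2", "age^3"]

    def test_continuous_exposure_adds_three_columns(self):
        X, terms = ht.build_design_matrix(self._panel(), ModelSpec())
        assert terms == ["Intercept", "age", "age^2", "age^3",
                         "no2", "no2:age", "no2:age^2"]

    def test_single_row_products(self):
        X, _ = ht.build_design_matrix(self._panel(), ModelSpec())
        row = X.iloc[0]
        assert list(row[["age", "age^2", "age^3"]]) == [10.0, 100.0, 1000.0]
        assert list(row[["no2", "no2:age", "no2:age^2"]]) == [2.0, 20.0, 200.0]

    def test_full_adjusted_layout_has_26_columns(self):
        cfg = ht.CohortConfig(n_participants=200, seed=17)
        panel = ht.generate_cohort(cfg)
        spec = ModelSpec(covariates=("female", "income_ratio", "less_than_hs",
                                     "indigenous", "smoker"),
                         missing_policy="listwise")
        X, terms = ht.build_design_matrix(panel, spec)
        # cubic age block + NO2 block (main, x age, x age^2) + four
        # covariates with cubic interactions + Indigenous with quadratic
        assert len(terms) == 26
        assert "indigenous:age^3" not in terms
        assert "smoker:age^3" in terms

    def test_missing_covariate_column_named(self):
        panel = self._panel().drop(columns="no2")
        with pytest.raises(KeyError, match="no2"):
            ht.build_design_matrix(panel, ModelSpec())

    def test_constant_column_warns_but_is_retained(self):
        panel = pd.DataFrame({"participant_id": [0, 1], "cycle": [1, 1],
                              "age": [30.0, 40.0], "no2": [5.0, 5.0]})
        with pytest.warns(UserWarning, match="constant"):
            X, terms = ht.build_design_matrix(panel, ModelSpec())
        assert "no2" in X.columns


class TestFit:
    def test_noise_free_recovery(self, clean_config):
        cfg = clean_config(seed=11, n=300, attrition="none", residual_sd=1e-8)
        cfg.random_effect_sd = {"intercept": 0.0, "age_slope": 0.0}
        panel = ht.generate_cohort(cfg)
        m = ht.GrowthCurveModel().fit(panel)
        truth = pd.Series(cfg.true_fixed_effects).reindex(m.beta_.index).fillna(0.0)
        assert (m.beta_ - truth).abs().max() < 1e-4

    def test_constant_weights_match_unweighted(self, small_clean_cohort):
        panel = small_clean_cohort
        ids = panel["participant_id"].unique()
        a = ht.GrowthCurveModel().fit(panel)
        b = ht.GrowthCurveModel().fit(panel, weights=pd.Series(2.5, index=ids))
        assert (a.beta_ - b.beta_).abs().max() < 1e-5
        assert a.loglik_ == pytest.approx(b.loglik_ / 2.5, rel=1e-6)

    def test_aic_definition_identity(self, small_clean_cohort):
        base = ht.GrowthCurveModel(exposure_form="none").fit(small_clean_cohort)
        full = ht.GrowthCurveModel(exposure_form="continuous").fit(small_clean_cohort)
        # AIC = -2 loglik + 2 k; the continuous spec adds exactly 3 terms
        k_base = (base.aic_ + 2 * base.loglik_) / 2
        k_full = (full.aic_ + 2 * full.loglik_) / 2
        assert k_full - k_base == pytest.approx(3.0, abs=1e-9)

    def test_agrees_with_statsmodels_mixedlm(self, small_clean_cohort):
        import statsmodels.formula.api as smf
        panel = small_clean_cohort
        m = ht.GrowthCurveModel().fit(panel)
        rows = m._analysis_rows(panel).copy()
        rows["a"] = (rows["age"] - 50) / 10
        pm = panel.groupby("participant_id")["no2"].mean()
        rows["no2pm"] = rows["participant_id"].map(pm)
        md = smf.mixedlm("hui ~ a + I(a**2) + I(a**3) + no2pm + no2pm:a "
                         "+ no2pm:I(a**2)", rows, groups=rows["participant_id"],
                         re_formula="~a")
        res = md.fit(reml=False, method="lbfgs")
        assert m.loglik_ == pytest.approx(res.llf, abs=0.05)
        assert m.beta_scaled_["Intercept"] == pytest.approx(
            res.fe_params["Intercept"], abs=2e-3)
        assert m.resid_var_ == pytest.approx(res.scale, rel=0.02)

    def test_rank_deficiency_reported(self, small_clean_cohort):
        panel = small_clean_cohort.copy()
        panel["no2"] = 7.0  # exposure block collinear with age block
        with pytest.raises(Exception, match="rank deficient"):
            ht.GrowthCurveModel().fit(panel)

    def test_predict_on_utility_scale_for_arcsine_outcome(self, small_clean_cohort):
        m = ht.GrowthCurveModel(outcome="arcsine_hui").fit(small_clean_cohort)
        pred = m.predict(small_clean_cohort[small_clean_cohort["cycle"] == 1])
        assert np.all(pred >= -0.36 - 1e-9) and np.all(pred <= 1.0 + 1e-9)


class TestBootstrapVcov:
    def test_identical_replicates_give_zero_vcov(self, small_clean_cohort):
        panel = small_clean_cohort
        ids = np.sort(panel["participant_id"].unique())
        w = pd.DataFrame({"weight": 1.0, "rep_1": 1.0, "rep_2": 1.0},
                         index=pd.Index(ids, name="participant_id"))
        m = ht.GrowthCurveModel().fit(panel)
        V = ht.bootstrap_vcov(panel, m, w)
        assert np.abs(V.to_numpy()).max() < 1e-16

    def test_diagonal_nonnegative_and_se_close_to_model_se(self, small_clean_cohort):
        panel = small_clean_cohort
        ids = np.sort(panel["participant_id"].unique())
        reps = ht.generate_bootstrap_weights(ids, 200, seed=13)
        m = ht.GrowthCurveModel().fit(panel)
        V = ht.bootstrap_vcov(panel, m, reps)
        d = np.diag(V.to_numpy())
        assert (d >= 0).all()
        se_boot = np.sqrt(V.loc["Intercept", "Intercept"])
        se_model = np.sqrt(m.vcov_.loc["Intercept", "Intercept"])
        assert se_boot == pytest.approx(se_model, rel=0.15)


class TestQuartiles:
    def test_cut_rule_matches_averaged_inverted_cdf(self):
        panel = pd.DataFrame({
            "participant_id": np.arange(8), "cycle": 1,
            "age": 40.0, "no2": np.arange(1.0, 9.0)})
        assert ht.quartile_cuts(panel) == pytest.approx((2.5, 4.5, 6.5))

    def test_tied_cuts_rejected(self):
        panel = pd.DataFrame({
            "participant_id": np.arange(8), "cycle": 1,
            "age": 40.0, "no2": np.ones(8)})
        with pytest.raises(ValueError, match="tied"):
            ht.quartile_cuts(panel)

    def test_quartile_fit_reports_aic_comparison(self, small_clean_cohort):
        qm, cuts, aics = ht.quartile_fit(small_clean_cohort, ht.GrowthCurveModel())
        assert set(aics) == {"continuous", "quartile"}
        assert len([t for t in qm.terms_ if t.startswith("no2_q")]) == 9
        assert cuts[0] < cuts[1] < cuts[2]

    def test_reference_quartile_profile_matches_unexposed_trajectory(self):
        beta = {"Intercept": 0.9, "age": -0.002,
                "no2_q2": -0.05, "no2_q3": -0.1, "no2_q4": -0.2}
        fe = ht.FixedEffects(beta)
        q1 = ht.Scenario(5.0, {"no2_q2": 0, "no2_q3": 0, "no2_q4": 0})
        base = ht.FixedEffects({"Intercept": 0.9, "age": -0.002})
        c1 = ht.predict_trajectory(fe, q1, 20, 80)
        c0 = ht.predict_trajectory(base, ht.Scenario(5.0), 20, 80)
        np.testing.assert_allclose(c1.values, c0.values)


class TestAicRetention:
    def test_candidate_overlap_rejected(self, small_clean_cohort):
        base = ht.GrowthCurveModel(covariates=("female",))
        with pytest.raises(ValueError, match="disjoint"):
            ht.aic_retention(small_clean_cohort, base, ("female",))

    def test_strong_effect_retained_noise_covariate_not(self, clean_config):
        cfg = clean_config(seed=77, n=1200, attrition="none")
        # strong female effect; smoking has no effect in the generator truth
        cfg.true_fixed_effects = dict(cfg.true_fixed_effects) | {"female": -0.08}
        panel = ht.generate_cohort(cfg)
        final, log = ht.aic_retention(panel, ht.GrowthCurveModel(),
                                      ("female", "smoker"))
        log = log.set_index("candidate")
        assert bool(log.loc["female", "retained"])
        assert "female" in final.covariates
        assert not bool(log.loc["smoker", "retained"])
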