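"""Differential attrition and survival: logistic models and inverse
probability weighting.

Longitudinal cohorts lose participants through death and non-response, and
both can depend on exposure and health.  Following the standard
inverse-probability-of-attrition approach, we model each participant's
probability of (a) surviving to the last cycle and (b) completing all
cycles, as a logistic function of the same baseline variables as the HUI
trajectory model, then refit the growth-curve model among the observed
participants weighted by the inverse of their fitted probability —
up-weighting the kinds of participants most likely to be lost.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from . import design as dz
from .growth import GrowthCurveModel

__all__ = [
    "participant_table",
    "AttritionModel",
    "fit_attrition_model",
    "compute_ip_weights",
    "weighted_refit",
]

DEFAULT_ATTRITION_COVARIATES = (
    "female", "income_ratio", "less_than_hs", "indigenous", "smoker")


def participant_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long panel to one row per participant.

    Baseline (cycle 1) covariates, exposure summaries (cycle-1 and
    period-mean NO2) and the two 9-cycle summary outcomes:
    ``survived`` (alive at the last cycle) and ``completed_all_cycles``
    (alive and still responding at the last cycle).
    """
    last_cycle = panel["cycle"].max()
    base = panel[panel["cycle"] == 1].set_index("participant_id")
    last = panel[panel["cycle"] == last_cycle].set_index("participant_id")
    out = base.copy()
    out["no2_cycle1"] = base["no2"]
    out["no2_period_mean"] = panel.groupby("participant_id")["no2"].mean()
    out["survived"] = last["alive"].astype(int)
    out["completed_all_cycles"] = (last["alive"] & last["responded"]).astype(int)
    return out.reset_index()


class AttritionModel(BaseEstimator):
    """Logistic regression of a 9-cycle summary outcome on baseline
    covariates and an exposure summary.

    Parameters
    ----------
    outcome : {"completed_all_cycles", "survived"}
    covariates : covariate names from the growth-model vocabulary
        (main effects only; age enters linearly).
    exposure_window : {"period_mean", "cycle1"} summary entering the model.
    """

    def __init__(self, outcome="completed_all_cycles",
                 covariates=DEFAULT_ATTRITION_COVARIATES,
                 exposure_window="period_mean"):
        self.outcome = outcome
        self.covariates = covariates
        self.exposure_window = exposure_window

    def _design(self, table: pd.DataFrame) -> pd.DataFrame:
        expo = ("no2_period_mean" if self.exposure_window == "period_mean"
                else "no2_cycle1")
        X = pd.DataFrame({"Intercept": 1.0, "no2": table[expo],
                          "age": table["age"]}, index=table.index)
        for cov in self.covariates:
            X[cov] = dz.covariate_series(table, cov).to_numpy()
        return X

    def fit(self, panel: pd.DataFrame, freq_weights=None):
        table = panel if "completed_all_cycles" in panel.columns \
            else participant_table(panel)
        y = table[self.outcome].to_numpy(float)
        if y.min() == y.max():
            raise ValueError(f"outcome {self.outcome!r} is constant; "
                             "logistic model is degenerate")
        X = self._design(table)
        glm = sm.GLM(y, X, family=sm.families.Binomial(),
                     freq_weights=freq_weights)
        res = glm.fit(maxiter=200)
        if np.any(np.abs(res.params) > 50):
            worst = res.params.abs().idxmax()
            raise ValueError(
                f"apparent complete separation (|coef| huge) for predictor "
                f"{worst!r}")
        self.terms_ = list(X.columns)
        self.params_ = res.params
        self.bse_ = res.bse
        self.vcov_ = pd.DataFrame(res.cov_params(), index=self.terms_,
                                  columns=self.terms_)
        self.n_ = len(table)
        self.result_ = res
        self.participant_ids_ = table["participant_id"].to_numpy()
        self.fitted_probs_ = pd.Series(res.fittedvalues.to_numpy(),
                                       index=self.participant_ids_)
        return self

    def predict_proba(self, panel: pd.DataFrame) -> pd.Series:
        table = panel if "completed_all_cycles" in panel.columns \
            else participant_table(panel)
        X = self._design(table)
        p = self.result_.predict(X)
        return pd.Series(np.asarray(p), index=table["participant_id"].to_numpy())

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.terms_,
                             "estimate": self.params_.to_numpy(),
                             "se": self.bse_.to_numpy(),
                             "p_value": self.result_.pvalues.to_numpy()})


def fit_attrition_model(panel, outcome="completed_all_cycles",
                        **kwargs) -> AttritionModel:
    """Functional wrapper over :class:`AttritionModel`."""
    return AttritionModel(outcome=outcome, **kwargs).fit(panel)


def compute_ip_weights(model: AttritionModel, panel: pd.DataFrame,
                       truncation_percentile: float | None = None) -> pd.Series:
    """Inverse-probability weights for the participants with the outcome.

    ``weight = 1 / p_hat`` for completers (or survivors), optionally
    truncated symmetrically at the given percentile, then normalised to
    mean 1.  Participants with numerically zero fitted probability raise
    unless truncation is requested.
    """
    table = panel if "completed_all_cycles" in panel.columns \
        else participant_table(panel)
    p = model.predict_proba(table)
    has_outcome = table.set_index("participant_id")[model.outcome] == 1
    p = p[has_outcome.to_numpy()]
    if truncation_percentile is None and np.any(p <= 1e-12):
        raise ValueError("fitted probability numerically zero; set "
                         "truncation_percentile for stability")
    w = 1.0 / np.clip(p, 1e-12, None)
    if truncation_percentile is not None:
        lo, hi = np.percentile(w, [truncation_percentile,
                                   100.0 - truncation_percentile])
        w = w.clip(lo, hi)
    w = w / w.mean()
    w.attrs["outcome"] = model.outcome
    w.attrs["truncation_percentile"] = truncation_percentile
    return w


def weighted_refit(panel: pd.DataFrame, model: GrowthCurveModel,
                   ip_weights: pd.Series, design_weights=None) -> GrowthCurveModel:
    """Refit a growth-curve model on the weighted observed subsample.

    The analysis set is the participants carrying an IP weight (completers
    or survivors); weights are the IP weights, optionally combined
    multiplicatively with design weights.
    """
    w = pd.Series(ip_weights, dtype=float)
    if design_weights is not None:
        dw = pd.Series(design_weights, dtype=float)
        w = w * dw.reindex(w.index)
    sub = panel[panel["participant_id"].isin(w.index)]
    refit = GrowthCurveModel(**model.get_params())
    return refit.fit(sub, weights=w)
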