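"""Random growth-curve model of HUI trajectory by age.

``GrowthCurveModel`` is a scikit-learn-style estimator: hyperparameters in
``__init__`` mirror :class:`~huitraj.design.ModelSpec`, ``fit`` takes a
long-format panel (one row per participant-cycle) and optional
per-participant weights, and fitted quantities carry trailing underscores
(``beta_``, ``vcov_``, ``loglik_``, ``aic_`` ...).  Internally age is
standardised (``(age - 50)/10``) before forming cubic polynomial columns;
coefficients and covariances are reported back on the raw-age scale so
they are directly comparable with published trajectory analyses.

Estimation is maximum likelihood (not REML) so that AIC comparisons
between fixed-effect specifications are valid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import design as dz
from ._lmm import ConvergenceError, fit_lmm, per_group_gls_moments
from .design import ModelSpec, build_design_matrix, transform_hui

log = logging.getLogger(__name__)

__all__ = [
    "GrowthCurveModel",
    "FixedEffects",
    "fit_growth_model",
    "aic_retention",
    "bootstrap_vcov",
    "quartile_cuts",
    "quartile_fit",
]


@dataclass
class FixedEffects:
    """A bare fixed-effects trajectory model (no fitting machinery).

    Enough for the QALY module: term names, coefficients, optionally a
    coefficient covariance, and the outcome scale the coefficients live on.
    """

    beta: pd.Series
    outcome: str = "raw_hui"
    vcov: pd.DataFrame | None = None

    def __post_init__(self):
        self.beta = pd.Series(self.beta, dtype=float)
        if "Intercept" not in self.beta.index:
            self.beta = pd.concat([pd.Series({"Intercept": 0.0}), self.beta])
        if self.vcov is not None:
            self.vcov = pd.DataFrame(self.vcov)

    @property
    def terms_(self):
        return list(self.beta.index)

    @property
    def beta_(self):
        return self.beta

    @property
    def vcov_(self):
        return self.vcov

    @property
    def outcome_(self):
        return self.outcome


def _age_z(age):
    return (np.asarray(age, float) - dz.AGE_CENTER) / dz.AGE_SCALE


class GrowthCurveModel(BaseEstimator):
    """Linear mixed model of HUI as a cubic polynomial of age with exposure
    and covariate blocks and participant random effects.

    Parameters mirror :class:`huitraj.design.ModelSpec`; see there for the
    vocabulary.  ``quartile_cuts_`` is set when ``exposure_form='quartile'``
    (supply ``cuts`` to :meth:`fit` or let it compute them).
    """

    def __init__(self, outcome="raw_hui", exposure_form="continuous",
                 exposure_window="period_mean", covariates=(),
                 interaction_orders=None, random_effects="intercept_and_age_slope",
                 missing_policy="category", maxiter=200):
        self.outcome = outcome
        self.exposure_form = exposure_form
        self.exposure_window = exposure_window
        self.covariates = covariates
        self.interaction_orders = interaction_orders
        self.random_effects = random_effects
        self.missing_policy = missing_policy
        self.maxiter = maxiter

    @property
    def spec(self) -> ModelSpec:
        kw = {}
        if self.interaction_orders is not None:
            kw["interaction_orders"] = dict(self.interaction_orders)
        return ModelSpec(
            outcome=self.outcome,
            exposure_form=self.exposure_form,
            exposure_window=self.exposure_window,
            covariates=tuple(self.covariates),
            random_effects=self.random_effects,
            missing_policy=self.missing_policy,
            **kw,
        )

    # -- fitting -----------------------------------------------------------

    def _analysis_rows(self, panel: pd.DataFrame) -> pd.DataFrame:
        rows = panel
        if "responded" in rows.columns:
            rows = rows[rows["responded"].astype(bool)]
        if "alive" in rows.columns:
            rows = rows[rows["alive"].astype(bool)]
        rows = rows[rows["hui"].notna()]
        if self.missing_policy == "listwise":
            for cov in self.covariates:
                source = dz._BINARY_DERIVATIONS.get(cov, (cov, None))[0]
                if source in rows.columns and rows[source].dtype == object:
                    rows = rows[rows[source] != "missing"]
        return rows

    def _prepare(self, panel: pd.DataFrame, cuts=None):
        """Assemble the numeric fitting problem once (reused by bootstrap
        replicate refits)."""
        spec = self.spec
        if spec.exposure_form != "none" and "no2_window" not in panel.columns \
                and "no2" in panel.columns:
            # evaluate the exposure window on the full panel (all cycles)
            # before restricting to observed rows
            panel = panel.assign(
                no2_window=dz.exposure_series(panel, spec.exposure_window))
        rows = self._analysis_rows(panel)
        if rows["participant_id"].nunique() < 2 or len(rows) < 2:
            raise ValueError("need >= 2 observations from >= 2 participants")
        if spec.exposure_form == "quartile" and cuts is None:
            cuts = quartile_cuts(rows, window=spec.exposure_window)
        X, terms = build_design_matrix(rows, spec, quartile_cuts=cuts,
                                       age_transform=_age_z)
        y = rows["hui"].to_numpy(float)
        if spec.outcome == "arcsine_hui":
            y = transform_hui(y)
        ids, group_idx = np.unique(rows["participant_id"].to_numpy(),
                                   return_inverse=True)
        return dict(X=X.to_numpy(), y=y, age_z=_age_z(rows["age"]),
                    group_idx=group_idx, ids=ids, terms=terms,
                    cuts=tuple(cuts) if cuts is not None else None)

    def _align_weights(self, weights, ids):
        if weights is None:
            return None
        wser = pd.Series(weights, dtype=float)
        missing = [i for i in ids if i not in wser.index]
        if missing:
            raise ValueError(
                f"weights missing for {len(missing)} participants "
                f"(e.g. {missing[:5]})"
            )
        return wser.reindex(ids).to_numpy()

    def fit(self, panel: pd.DataFrame, weights=None, *, cuts=None, theta0=None):
        """Fit by weighted maximum likelihood.

        Parameters
        ----------
        panel : long-format panel with at least participant_id, cycle, age,
            hui and the columns the covariates need.
        weights : optional per-participant weights — a mapping or
            :class:`pandas.Series` indexed by participant_id.  Each
            participant's log-likelihood contribution is multiplied by its
            weight; a constant weight reproduces the unweighted fit.
        cuts : quartile cutpoints when ``exposure_form='quartile'``
            (computed from the analysis sample if omitted).
        """
        prep = self._prepare(panel, cuts)
        self.quartile_cuts_ = prep["cuts"]
        terms = prep["terms"]
        w = self._align_weights(weights, prep["ids"])
        res = fit_lmm(
            prep["X"], prep["y"], prep["age_z"], prep["group_idx"], w,
            slope=self.spec.random_effects == "intercept_and_age_slope",
            theta0=theta0, maxiter=self.maxiter,
        )

        T = dz.age_rescale_matrix(terms)
        beta_raw = T @ res.beta
        vcov_raw = T @ res.cov_beta @ T.T
        self.terms_ = terms
        self.beta_ = pd.Series(beta_raw, index=terms)
        self.vcov_ = pd.DataFrame(vcov_raw, index=terms, columns=terms)
        self.beta_scaled_ = pd.Series(res.beta, index=terms)
        self.re_cov_ = res.re_cov          # on (intercept, (age-50)/10) scale
        self.resid_var_ = res.sigma2
        self.loglik_ = res.loglik
        self.aic_ = res.aic
        self.n_obs_ = res.n_obs
        self.n_participants_ = res.n_groups
        self.theta_ = res.theta
        self.converged_ = res.converged
        self.outcome_ = self.outcome
        return self

    # -- prediction --------------------------------------------------------

    def predict(self, panel: pd.DataFrame) -> np.ndarray:
        """Population-level (fixed-effects) prediction on the utility scale."""
        X = dz.evaluate_terms(panel, self.terms_,
                              exposure_window=self.exposure_window,
                              quartile_cuts=self.quartile_cuts_)
        eta = X.to_numpy() @ self.beta_.to_numpy()
        if self.outcome_ == "arcsine_hui":
            return dz.inverse_transform_hui(eta)
        return eta

    def coefficient_table(self) -> pd.DataFrame:
        """Term, estimate, SE and normal-reference two-sided p-value."""
        se = np.sqrt(np.clip(np.diag(self.vcov_.to_numpy()), 0, None))
        from scipy.stats import norm
        z = np.divide(self.beta_.to_numpy(), se, out=np.full_like(se, np.nan),
                      where=se > 0)
        return pd.DataFrame({
            "term": self.terms_,
            "estimate": self.beta_.to_numpy(),
            "se": se,
            "p_value": 2 * norm.sf(np.abs(z)),
        })


def fit_growth_model(panel, spec: ModelSpec | None = None, weights=None,
                     **spec_kwargs) -> GrowthCurveModel:
    """Functional wrapper over :class:`GrowthCurveModel`."""
    if spec is not None:
        spec_kwargs = dict(
            outcome=spec.outcome, exposure_form=spec.exposure_form,
            exposure_window=spec.exposure_window, covariates=spec.covariates,
            interaction_orders=dict(spec.interaction_orders),
            random_effects=spec.random_effects,
            missing_policy=spec.missing_policy,
        ) | spec_kwargs
    return GrowthCurveModel(**spec_kwargs).fit(panel, weights=weights)


# -- AIC covariate retention ------------------------------------------------

def aic_retention(panel, base_model: GrowthCurveModel, candidates,
                  weights=None):
    """Forward covariate retention by AIC.

    For each candidate (in the given order) refit the current model with the
    candidate's main effect and age-interaction block added; retain the
    candidate iff the AIC strictly decreases.  Returns the final fitted
    model and a per-candidate log DataFrame.
    """
    current = GrowthCurveModel(**base_model.get_params())
    current.fit(panel, weights=weights)
    records = []
    kept = list(current.covariates)
    if set(kept) & set(candidates):
        raise ValueError("candidates must be disjoint from base covariates")
    for cand in candidates:
        trial = GrowthCurveModel(**current.get_params())
        trial.covariates = tuple(kept) + (cand,)
        try:
            trial.fit(panel, weights=weights)
        except Exception as exc:  # candidate skipped, reason logged
            records.append(dict(candidate=cand, aic_without=current.aic_,
                                aic_with=np.nan, retained=False,
                                note=f"fit failed: {exc}"))
            continue
        retained = trial.aic_ < current.aic_
        records.append(dict(candidate=cand, aic_without=current.aic_,
                            aic_with=trial.aic_, retained=retained, note=""))
        if retained:
            current = trial
            kept.append(cand)
    return current, pd.DataFrame(records)


# -- survey bootstrap variance ----------------------------------------------

def bootstrap_vcov(panel, model: GrowthCurveModel, replicate_weights: pd.DataFrame,
                   max_failures=0.10, reestimate_variance=False) -> pd.DataFrame:
    """Design-based coefficient covariance from bootstrap replicate weights.

    Refits the model's point estimates under each replicate weight column
    and returns the empirical covariance of replicate estimates around the
    main-weight estimate, ``(1/B) sum_b (beta_b - beta)(beta_b - beta)'``.
    Replaces the model-based ``vcov_`` in design-based inference.

    By default each replicate re-solves the weighted GLS fixed effects at
    the main-fit variance parameters (fixed effects and variance
    components are asymptotically orthogonal in the linear mixed model);
    ``reestimate_variance=True`` re-optimises the variance parameters per
    replicate as well.

    ``replicate_weights`` is a DataFrame indexed by participant_id with a
    ``weight`` column (main weights) and one column per replicate.
    """
    main = replicate_weights["weight"]
    fitted = GrowthCurveModel(**model.get_params())
    fitted.fit(panel, weights=main, cuts=getattr(model, "quartile_cuts_", None))
    beta0 = fitted.beta_.to_numpy()
    theta0 = fitted.theta_
    slope = fitted.random_effects == "intercept_and_age_slope"
    prep = fitted._prepare(panel, fitted.quartile_cuts_)
    T = dz.age_rescale_matrix(prep["terms"])
    rep_cols = [c for c in replicate_weights.columns if c != "weight"]
    deltas = []
    failures = []
    if not reestimate_variance:
        G, h = per_group_gls_moments(prep["X"], prep["y"], prep["age_z"],
                                     prep["group_idx"], theta0, slope=slope)
    for c in rep_cols:
        try:
            w = fitted._align_weights(replicate_weights[c], prep["ids"])
            if reestimate_variance:
                res = fit_lmm(prep["X"], prep["y"], prep["age_z"],
                              prep["group_idx"], w, slope=slope, theta0=theta0,
                              maxiter=fitted.maxiter)
                beta_s = res.beta
            else:
                beta_s = np.linalg.solve(
                    np.einsum("g,gpq->pq", w, G), np.einsum("g,gp->p", w, h))
            deltas.append(T @ beta_s - beta0)
        except (ConvergenceError, np.linalg.LinAlgError) as exc:
            failures.append((c, str(exc)))
    if len(failures) > max_failures * len(rep_cols):
        raise ConvergenceError(
            f"{len(failures)}/{len(rep_cols)} bootstrap replicates failed "
            f"(first: {failures[0]})"
        )
    if failures:
        warnings.warn(f"dropped {len(failures)} non-converged bootstrap "
                      "replicates", stacklevel=2)
    D = np.asarray(deltas)
    V = D.T @ D / len(D)
    return pd.DataFrame(V, index=fitted.terms_, columns=fitted.terms_)


# -- quartile exposure specification ----------------------------------------

def quartile_cuts(panel, window="period_mean") -> tuple[float, float, float]:
    """Exposure quartile cutpoints from the analysis sample.

    Computed on one value per participant (the spec'd exposure window)
    using averaged-inverted-CDF sample quantiles, i.e. the inverse
    empirical CDF with averaging at discontinuities (for exposures 1..8
    this gives cuts 2.5/4.5/6.5).
    """
    per = (panel.assign(_e=dz.exposure_series(panel, window))
                .groupby("participant_id")["_e"].first())
    c = np.quantile(per.to_numpy(float), [0.25, 0.5, 0.75],
                    method="averaged_inverted_cdf")
    if not (c[0] < c[1] < c[2]):
        raise ValueError(f"tied exposure quartile cutpoints {c.tolist()}")
    return tuple(float(v) for v in c)


def quartile_fit(panel, model: GrowthCurveModel, weights=None):
    """Refit with exposure specified by quartile (Q1 reference; Q2-Q4
    indicators each with main effect and age, age^2 interactions).

    Returns ``(quartile_model, cuts, aic_comparison)`` where the comparison
    maps {'continuous', 'quartile'} to AIC so the concentration-response
    shape can be judged against the continuous specification.
    """
    cont = GrowthCurveModel(**model.get_params())
    cont.exposure_form = "continuous"
    cont.fit(panel, weights=weights)
    cuts = quartile_cuts(cont._analysis_rows(panel), window=model.exposure_window)
    quart = GrowthCurveModel(**model.get_params())
    quart.exposure_form = "quartile"
    quart.fit(panel, weights=weights, cuts=cuts)
    return quart, cuts, {"continuous": cont.aic_, "quartile": quart.aic_}
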