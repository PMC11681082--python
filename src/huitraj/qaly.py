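"""QALY quantification from fitted HUI trajectories.

Quality-adjusted life years are years of life weighted by utility: one
year lived at HUI ``u`` contributes ``u`` QALYs, so QALYs lived between
two ages are the area under the HUI-by-age curve.  This module predicts
trajectories under exposure scenarios from a fitted growth-curve model,
integrates them (natural/not-a-knot cubic spline, trapezoid, or left-step
rules), contrasts scenarios per person and at the population level via a
life table and age pyramid, and propagates coefficient uncertainty by
Monte Carlo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .design import HUI_CEILING, HUI_FLOOR, inverse_transform_hui, parse_term

log = logging.getLogger(__name__)

__all__ = [
    "Scenario",
    "TrajectoryCurve",
    "LifeTable",
    "predict_trajectory",
    "trajectory_difference",
    "auc",
    "qaly_per_person",
    "delta_qaly",
    "population_qaly",
    "monte_carlo_uncertainty",
]


@dataclass(frozen=True)
class Scenario:
    """An exposure scenario: an NO2 concentration and a fixed covariate
    profile (covariate name -> value) at which the trajectory is evaluated."""

    no2_ppb: float
    covariate_profile: dict = field(default_factory=dict)
    label: str = ""

    def __post_init__(self):
        if self.no2_ppb <= 0:
            raise ValueError("no2_ppb must be > 0")


@dataclass
class TrajectoryCurve:
    """Predicted HUI by age on a uniform age grid under one scenario."""

    ages: np.ndarray
    values: np.ndarray
    scenario: Scenario | None = None

    def __post_init__(self):
        self.ages = np.asarray(self.ages, float)
        self.values = np.asarray(self.values, float)
        if self.ages.shape != self.values.shape:
            raise ValueError("ages and values must have equal length")
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("age grid must be strictly increasing")


@dataclass
class LifeTable:
    """Survival probability by single year of age (from the table's radix).

    ``survival`` maps age -> cumulative survival probability l(age)/l(0);
    probabilities must be in [0, 1] and non-increasing in age.
    """

    survival: pd.Series

    def __post_init__(self):
        s = pd.Series(self.survival, dtype=float).sort_index()
        if s.min() < 0 or s.max() > 1:
            raise ValueError("survival probabilities must be in [0, 1]")
        if np.any(np.diff(s.to_numpy()) > 1e-12):
            raise ValueError("survival must be non-increasing in age")
        self.survival = s

    @classmethod
    def from_csv(cls, path):
        df = pd.read_csv(path)
        return cls(pd.Series(df.iloc[:, 1].to_numpy(),
                             index=df.iloc[:, 0].to_numpy()))

    def conditional(self, ages, baseline_age) -> np.ndarray:
        """P(alive at each of ``ages`` | alive at ``baseline_age``)."""
        ages = np.asarray(ages)
        missing = [int(a) for a in ages if a not in self.survival.index]
        if baseline_age not in self.survival.index:
            missing.append(int(baseline_age))
        if missing:
            raise ValueError(f"life table missing ages {sorted(set(missing))}")
        s0 = self.survival.loc[baseline_age]
        return self.survival.loc[ages].to_numpy() / max(s0, 1e-300)


def _scenario_row(model, scenario: Scenario):
    """Per-term covariate values implied by a scenario."""
    vals = {}
    for term in model.terms_:
        cov, _ = parse_term(term)
        if cov in vals:
            continue
        if cov == "1":
            vals[cov] = 1.0
        elif cov == "no2":
            vals[cov] = float(scenario.no2_ppb)
        elif cov in scenario.covariate_profile:
            vals[cov] = float(scenario.covariate_profile[cov])
        elif cov.endswith("_missing"):
            vals[cov] = 0.0
        else:
            raise KeyError(
                f"scenario profile missing covariate {cov!r} required by the "
                f"model (profile has {sorted(scenario.covariate_profile)})")
    return vals


def _design_grid(model, scenario, ages):
    vals = _scenario_row(model, scenario)
    cols = []
    for term in model.terms_:
        cov, power = parse_term(term)
        cols.append(vals[cov] * ages**power)
    return np.column_stack(cols)


def predict_trajectory(model, scenario: Scenario, age_min=20.0, age_max=80.0,
                       step=1.0) -> TrajectoryCurve:
    """Evaluate the fixed-effects trajectory on a uniform age grid.

    Exposure and covariates are held fixed at the scenario values; models
    fitted on the arcsine scale are back-transformed to utilities.  Values
    outside the HUI range [-0.36, 1] are clipped (clip events logged).
    """
    ages = np.arange(age_min, age_max + step / 2.0, step)
    D = _design_grid(model, scenario, ages)
    eta = D @ model.beta_.to_numpy()
    outcome = getattr(model, "outcome_", getattr(model, "outcome", "raw_hui"))
    values = inverse_transform_hui(eta) if outcome == "arcsine_hui" else eta
    n_clip = int(np.sum((values < HUI_FLOOR) | (values > HUI_CEILING)))
    if n_clip:
        log.info("predict_trajectory: clipped %d of %d grid values to the "
                 "HUI range", n_clip, len(values))
        values = np.clip(values, HUI_FLOOR, HUI_CEILING)
    return TrajectoryCurve(ages, values, scenario)


def trajectory_difference(ref: TrajectoryCurve, alt: TrajectoryCurve) -> TrajectoryCurve:
    """Pointwise difference curve (reference minus alternative)."""
    if not np.array_equal(ref.ages, alt.ages):
        raise ValueError("curves must share an age grid")
    return TrajectoryCurve(ref.ages, ref.values - alt.values)


def auc(curve: TrajectoryCurve, method: str = "spline", *,
        spline_bc: str = "not-a-knot") -> float:
    """Area under a trajectory curve, in utility-years (QALYs).

    ``trapezoid`` is the composite trapezoid rule; ``step`` sums
    left-value rectangles; ``spline`` integrates a cubic interpolating
    spline in closed form (default boundary condition "not-a-knot",
    which reproduces single cubic polynomials exactly; "natural" is
    available via ``spline_bc``).
    """
    x, y = curve.ages, curve.values
    if len(x) < 2:
        raise ValueError("need >= 2 grid points")
    if method == "trapezoid":
        return float(np.trapezoid(y, x))
    if method == "step":
        return float(np.sum(y[:-1] * np.diff(x)))
    if method == "spline":
        if len(x) < 4:
            raise ValueError("spline AUC needs >= 4 grid points")
        cs = CubicSpline(x, y, bc_type=spline_bc)
        return float(cs.integrate(x[0], x[-1]))
    raise ValueError(f"unknown AUC method {method!r}")


def qaly_per_person(model, scenario: Scenario, age_range=(20.0, 80.0),
                    method="spline", step=1.0, clip_to_unit=False) -> float:
    """QALYs lived per person over an age range under a scenario.

    Integrates the predicted trajectory; ``clip_to_unit`` optionally clips
    predicted HUI to [0, 1] before integration (off by default; clip
    events logged).
    """
    curve = predict_trajectory(model, scenario, *age_range, step=step)
    if clip_to_unit:
        n_clip = int(np.sum((curve.values < 0) | (curve.values > 1)))
        if n_clip:
            log.info("qaly_per_person: clipped %d grid values to [0, 1]", n_clip)
        curve = TrajectoryCurve(curve.ages, np.clip(curve.values, 0.0, 1.0),
                                scenario)
    return auc(curve, method)


def delta_qaly(model, scenario_ref: Scenario, scenario_alt: Scenario,
               age_range=(20.0, 80.0), method="spline", step=1.0,
               clip_to_unit=False) -> dict:
    """QALY contrast between two scenarios sharing a covariate profile.

    Returns absolute difference (reference minus alternative), percent of
    the reference, and the per-scenario QALYs.
    """
    if scenario_ref.covariate_profile != scenario_alt.covariate_profile:
        raise ValueError("scenarios must share a covariate profile")
    q_ref = qaly_per_person(model, scenario_ref, age_range, method, step,
                            clip_to_unit)
    q_alt = qaly_per_person(model, scenario_alt, age_range, method, step,
                            clip_to_unit)
    absolute = q_ref - q_alt
    percent = float("nan")
    if q_ref == 0:
        log.warning("delta_qaly: reference QALYs are zero; percent undefined")
    else:
        percent = 100.0 * absolute / q_ref
    return {"qaly_ref": q_ref, "qaly_alt": q_alt,
            "absolute": absolute, "percent": percent}


def population_qaly(delta_curve: TrajectoryCurve, pyramid: pd.Series,
                    life_table: LifeTable, horizon_age: float = 80.0,
                    min_age: float = 20.0, include_younger: bool = False,
                    year_count: str = "inclusive") -> float:
    """Population-total QALY difference as the current population ages.

    For each baseline-age cohort, sums ``count_a * S(y | a) * dHUI(y)``
    over future ages ``y`` from ``max(min_age, a)`` to the horizon,
    using life-table conditional survival.  Conservative accounting: only
    the supplied baseline population, no births or immigration.  Cohorts
    younger than ``min_age`` are excluded unless ``include_younger``
    (they then contribute from ``min_age`` on).  ``year_count``:
    "inclusive" counts both endpoint ages as lived years (the documented
    default convention); "exclusive_end" drops the horizon endpoint.
    """
    if year_count not in ("inclusive", "exclusive_end"):
        raise ValueError(f"unknown year_count {year_count!r}")
    pyramid = pd.Series(pyramid, dtype=float).sort_index()
    ages = delta_curve.ages
    dhui = pd.Series(delta_curve.values, index=ages)
    total = 0.0
    for a, count in pyramid.items():
        if a > horizon_age:
            continue
        if a < min_age and not include_younger:
            continue
        start = max(min_age, a)
        end = horizon_age if year_count == "inclusive" else horizon_age - 1
        ys = [y for y in ages if start <= y <= end]
        if not ys:
            continue
        surv = life_table.conditional(ys, a if a in life_table.survival.index
                                      else start)
        total += count * float(np.sum(surv * dhui.loc[ys].to_numpy()))
    return total


def monte_carlo_uncertainty(model, scenario_ref: Scenario,
                            scenario_alt: Scenario, age_range=(20.0, 80.0),
                            method="spline", step=1.0, n_iter: int = 1000,
                            seed=0, coef_block: str = "exposure") -> dict:
    """Monte-Carlo uncertainty for the per-person QALY contrast.

    Samples the NO2-related coefficient block (or the full coefficient
    vector with ``coef_block='full'``) from a multivariate normal with the
    model's coefficient covariance (bootstrap vcov when attached),
    recomputes the QALY delta per draw, and reports the percentile 95%
    interval and an add-one-corrected two-sided Monte-Carlo p-value
    ``min(1, 2 * min(#(d<=0)+1, #(d>=0)+1) / (n_iter+1))``.
    Seed-deterministic; a zero covariance yields a width-zero interval.
    """
    if model.vcov_ is None:
        raise ValueError("model carries no coefficient covariance")
    rng = np.random.default_rng(seed)
    terms = list(model.terms_)
    beta = model.beta_.to_numpy().copy()
    V = model.vcov_.loc[terms, terms].to_numpy()
    if coef_block == "exposure":
        block = [i for i, t in enumerate(terms)
                 if parse_term(t)[0].startswith("no2")]
        if not block:
            raise ValueError("model has no NO2-related terms")
    elif coef_block == "full":
        block = list(range(len(terms)))
    else:
        raise ValueError(f"unknown coef_block {coef_block!r}")
    Vb = V[np.ix_(block, block)]
    evals, evecs = np.linalg.eigh((Vb + Vb.T) / 2.0)
    if evals.min() < -1e-8 * max(evals.max(), 1e-300):
        raise ValueError("coefficient covariance is not positive semidefinite")
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    draws = beta[None, :].repeat(n_iter, axis=0)
    draws[:, block] = beta[block] + rng.standard_normal((n_iter, len(block))) @ root.T

    ages = np.arange(age_range[0], age_range[1] + step / 2.0, step)
    D_ref = _design_grid(model, scenario_ref, ages)
    D_alt = _design_grid(model, scenario_alt, ages)
    outcome = getattr(model, "outcome_", getattr(model, "outcome", "raw_hui"))

    def curves(D):
        eta = draws @ D.T                      # (n_iter, n_ages)
        return inverse_transform_hui(eta) if outcome == "arcsine_hui" else eta

    y_ref, y_alt = curves(D_ref), curves(D_alt)
    deltas = np.empty(n_iter)
    for i in range(n_iter):
        deltas[i] = (auc(TrajectoryCurve(ages, y_ref[i]), method)
                     - auc(TrajectoryCurve(ages, y_alt[i]), method))
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    n_le = int(np.sum(deltas <= 0))
    n_ge = int(np.sum(deltas >= 0))
    p = min(1.0, 2.0 * min(n_le + 1, n_ge + 1) / (n_iter + 1))
    return {"mean": float(deltas.mean()), "ci_low": float(lo),
            "ci_high": float(hi), "p_value": p, "draws": deltas}
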