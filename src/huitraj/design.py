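"""Model specification, HUI transform and design-matrix construction.

The trajectory model is a cubic polynomial in age with optional exposure
and covariate blocks, each block consisting of a main effect and products
with powers of age:

    E[HUI] = b0 + b1*age + b2*age^2 + b3*age^3
             + sum_j b_j * x_j
             + sum_j sum_p b_jp * x_j * age^p        (p up to 3 per covariate)

Term names are stable strings: ``"age^2"``, ``"no2:age"``, ``"smoker:age^3"``
etc.  A term is a covariate name optionally multiplied by a power of age,
written ``cov:age^p``; the age polynomial itself is the block of the
implicit covariate ``1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from math import comb
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

HUI_FLOOR = -0.36
HUI_CEILING = 1.0

# Internal age standardization for numerically stable cubic fits.
AGE_CENTER = 50.0
AGE_SCALE = 10.0

#: Default maximum age power per covariate block (exposure interacts with
#: age and age^2 only; Indigenous identity likewise; others cubic).
DEFAULT_INTERACTION_ORDERS: dict[str, int] = {
    "no2": 2,
    "female": 3,
    "income_ratio": 3,
    "less_than_hs": 3,
    "indigenous": 2,
    "smoker": 3,
    "active": 2,
    "moderate": 2,
    "activity_score": 2,
}

#: Covariates derivable from raw panel columns (reference levels: male,
#: education above high school, non-Indigenous, non-smoker, inactive).
_BINARY_DERIVATIONS: dict[str, tuple[str, tuple[str, ...]]] = {
    "female": ("sex", ("female",)),
    "less_than_hs": ("education", ("less_than_high_school",)),
    "indigenous": ("racialized_group", ("indigenous",)),
    "smoker": ("smoking", ("daily", "occasionally")),
    "active": ("activity_category", ("active",)),
    "moderate": ("activity_category", ("moderate",)),
}

_NUMERIC_COVARIATES = ("income_ratio", "work_exertion_score", "activity_score", "no2")


def transform_hui(h):
    """Arcsine-transform HUI utilities: arcsin(2*(h + 0.36)/1.36 - 1).

    Strictly increasing map of [-0.36, 1] onto [-pi/2, pi/2]; used as a
    variance-stabilising sensitivity outcome.  Raises ``ValueError`` naming
    the offending positions for inputs outside the HUI range.
    """
    arr = np.asarray(h, dtype=float)
    bad = (arr < HUI_FLOOR - 1e-12) | (arr > HUI_CEILING + 1e-12)
    bad &= ~np.isnan(arr)
    if np.any(bad):
        idx = np.flatnonzero(np.atleast_1d(bad))[:10]
        raise ValueError(
            f"HUI values outside [{HUI_FLOOR}, {HUI_CEILING}] at positions "
            f"{idx.tolist()}"
        )
    u = 2.0 * (arr + 0.36) / 1.36 - 1.0
    out = np.arcsin(np.clip(u, -1.0, 1.0))
    return out if out.ndim else float(out)


def inverse_transform_hui(t):
    """Inverse of :func:`transform_hui`: map [-pi/2, pi/2] back to utilities."""
    arr = np.asarray(t, dtype=float)
    out = 1.36 * (np.sin(arr) + 1.0) / 2.0 - 0.36
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ModelSpec:
    """Specification of a growth-curve model's fixed-effect structure.

    Parameters
    ----------
    outcome : {"raw_hui", "arcsine_hui"}
    exposure_form : {"none", "continuous", "quartile"}
    exposure_window : {"period_mean", "cycle1"}
        Whether each participant's NO2 regressor is their mean exposure
        over all cycles or the cycle-1 value.
    covariates : ordered covariate names (term-name vocabulary above).
    interaction_orders : covariate -> max age power (0..3).
    random_effects : {"intercept_only", "intercept_and_age_slope"}
    missing_policy : {"category", "listwise"}
        Explicit missing-indicator columns vs. dropping rows with a
        missing covariate category.
    """

    outcome: str = "raw_hui"
    exposure_form: str = "continuous"
    exposure_window: str = "period_mean"
    covariates: tuple[str, ...] = ()
    interaction_orders: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_INTERACTION_ORDERS)
    )
    random_effects: str = "intercept_and_age_slope"
    missing_policy: str = "category"

    def __post_init__(self):
        if self.outcome not in ("raw_hui", "arcsine_hui"):
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.exposure_form not in ("none", "continuous", "quartile"):
            raise ValueError(f"unknown exposure_form {self.exposure_form!r}")
        if self.exposure_window not in ("period_mean", "cycle1"):
            raise ValueError(f"unknown exposure_window {self.exposure_window!r}")
        if self.random_effects not in ("intercept_only", "intercept_and_age_slope"):
            raise ValueError(f"unknown random_effects {self.random_effects!r}")
        if self.missing_policy not in ("category", "listwise"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        for cov, order in dict(self.interaction_orders).items():
            if order not in (0, 1, 2, 3):
                raise ValueError(f"interaction order for {cov!r} must be 0..3")

    def order_for(self, cov: str) -> int:
        return int(dict(self.interaction_orders).get(cov, 3))

    def with_covariates(self, covariates: Sequence[str]) -> "ModelSpec":
        return replace(self, covariates=tuple(covariates))


def parse_term(term: str) -> tuple[str, int]:
    """Split a term name into (covariate, age power).

    ``"age^2" -> ("1", 2)``; ``"no2:age" -> ("no2", 1)``; ``"smoker" ->
    ("smoker", 0)``; ``"Intercept" -> ("1", 0)``.
    """
    if term in ("Intercept", "1"):
        return "1", 0
    parts = term.split(":")
    power = 0
    cov = "1"
    for part in parts:
        if part == "age":
            power += 1
        elif part.startswith("age^"):
            power += int(part[4:])
        else:
            cov = part
    return cov, power


def term_name(cov: str, power: int) -> str:
    if cov == "1":
        if power == 0:
            return "Intercept"
        return "age" if power == 1 else f"age^{power}"
    if power == 0:
        return cov
    return f"{cov}:age" if power == 1 else f"{cov}:age^{power}"


def exposure_series(panel: pd.DataFrame, window: str) -> pd.Series:
    """Per-row NO2 regressor under the chosen exposure window.

    A precomputed ``no2_window`` column takes precedence, so callers can
    evaluate the window on the full panel before restricting to analysis
    rows (the period mean is over all cycles, observed or not).
    """
    if "no2_window" in panel.columns:
        return panel["no2_window"].astype(float)
    if "no2" not in panel.columns:
        raise KeyError("panel has no 'no2' column")
    if window == "cycle1":
        c1 = panel.loc[panel["cycle"] == 1].set_index("participant_id")["no2"]
        return panel["participant_id"].map(c1)
    grp = panel.groupby("participant_id")["no2"].mean()
    return panel["participant_id"].map(grp)


def covariate_series(panel: pd.DataFrame, cov: str, *, exposure_window: str = "period_mean") -> pd.Series:
    """Numeric column for a covariate name; raises ``KeyError`` listing the
    known vocabulary if the name is unresolvable."""
    if cov == "1":
        return pd.Series(1.0, index=panel.index)
    if cov == "no2":
        return exposure_series(panel, exposure_window).astype(float)
    if cov in _BINARY_DERIVATIONS:
        source, levels = _BINARY_DERIVATIONS[cov]
        if source not in panel.columns:
            raise KeyError(f"panel lacks column {source!r} needed for covariate {cov!r}")
        return panel[source].isin(levels).astype(float)
    if cov.endswith("_missing"):
        base = cov[: -len("_missing")]
        if base in _BINARY_DERIVATIONS:
            source, _ = _BINARY_DERIVATIONS[base]
        else:
            source = base
        if source not in panel.columns:
            raise KeyError(f"panel lacks column {source!r} needed for covariate {cov!r}")
        return (panel[source] == "missing").astype(float)
    if cov in _NUMERIC_COVARIATES or cov in panel.columns:
        if cov not in panel.columns:
            raise KeyError(f"panel lacks column {cov!r}")
        return pd.to_numeric(panel[cov], errors="raise").astype(float)
    known = sorted(set(_BINARY_DERIVATIONS) | set(_NUMERIC_COVARIATES) | {"1"})
    raise KeyError(f"unknown covariate {cov!r}; known covariate names: {known}")


def evaluate_terms(panel: pd.DataFrame, terms: Sequence[str], *,
                   exposure_window: str = "period_mean",
                   age_transform: Callable[[np.ndarray], np.ndarray] | None = None,
                   quartile_cuts: Sequence[float] | None = None) -> pd.DataFrame:
    """Evaluate term columns on a panel.

    ``age_transform`` maps raw age (years) to the scale used for the age
    powers (identity by default; the fitter passes the standardization).
    """
    age = panel["age"].to_numpy(dtype=float)
    a = age if age_transform is None else age_transform(age)
    cols = {}
    cov_cache: dict[str, np.ndarray] = {}
    for term in terms:
        cov, power = parse_term(term)
        if cov not in cov_cache:
            if cov.startswith("no2_q"):
                cov_cache[cov] = _quartile_indicator(panel, cov, quartile_cuts,
                                                    exposure_window)
            else:
                cov_cache[cov] = covariate_series(
                    panel, cov, exposure_window=exposure_window
                ).to_numpy(dtype=float)
        cols[term] = cov_cache[cov] * a**power
    return pd.DataFrame(cols, index=panel.index)


def _quartile_indicator(panel, cov, cuts, window):
    if cuts is None:
        raise ValueError(f"term {cov!r} requires quartile cuts")
    expo = exposure_series(panel, window).to_numpy(dtype=float)
    q = int(cov[len("no2_q"):])
    c1, c2, c3 = cuts
    bins = np.digitize(expo, [c1, c2, c3], right=True) + 1  # 1..4
    return (bins == q).astype(float)


def spec_terms(panel: pd.DataFrame, spec: ModelSpec) -> list[str]:
    """Ordered term names implied by a :class:`ModelSpec` on a panel."""
    terms = ["Intercept", "age", "age^2", "age^3"]
    if spec.exposure_form == "continuous":
        terms += [term_name("no2", p) for p in range(0, spec.order_for("no2") + 1)]
    elif spec.exposure_form == "quartile":
        for q in (2, 3, 4):
            terms += [term_name(f"no2_q{q}", p) for p in range(0, 3)]
    for cov in spec.covariates:
        terms += [term_name(cov, p) for p in range(0, spec.order_for(cov) + 1)]
        if spec.missing_policy == "category":
            source = _BINARY_DERIVATIONS.get(cov, (cov, None))[0]
            if source in panel.columns and (panel[source] == "missing").any():
                terms.append(f"{cov}_missing")
    # activity expands to two indicators sharing one source; deduplicate
    seen, ordered = set(), []
    for t in terms:
        if t not in seen:
            seen.add(t)
            ordered.append(t)
    return ordered


def build_design_matrix(panel: pd.DataFrame, spec: ModelSpec, *,
                        quartile_cuts: Sequence[float] | None = None,
                        age_transform: Callable | None = None
                        ) -> tuple[pd.DataFrame, list[str]]:
    """Build the fixed-effects design matrix for a panel under a spec.

    Returns the matrix (one row per panel row, one column per term, stable
    term-name columns) and the term list.  Constant columns other than the
    intercept are retained with a warning.
    """
    terms = spec_terms(panel, spec)
    X = evaluate_terms(panel, terms, exposure_window=spec.exposure_window,
                       age_transform=age_transform, quartile_cuts=quartile_cuts)
    for t in terms[1:]:
        col = X[t].to_numpy()
        if len(col) > 1 and np.nanstd(col) == 0.0:
            warnings.warn(f"design column {t!r} is constant", stacklevel=2)
    return X, terms


def age_rescale_matrix(terms: Sequence[str]) -> np.ndarray:
    """Linear map T with beta_raw = T @ beta_scaled.

    The fitter estimates coefficients of ``a^p`` with ``a = (age - c)/s``;
    expanding ``a^p = sum_q C(p,q) (-c)^(p-q) s^(-p) age^q`` within each
    covariate block gives the raw-age coefficients reported to users.
    """
    c, s = AGE_CENTER, AGE_SCALE
    k = len(terms)
    parsed = [parse_term(t) for t in terms]
    index = {pt: i for i, pt in enumerate(parsed)}
    T = np.zeros((k, k))
    for j, (cov, p) in enumerate(parsed):
        for q in range(p + 1):
            i = index.get((cov, q))
            if i is None:
                raise ValueError(
                    f"term block for {cov!r} lacks age power {q}; blocks must "
                    "be downward-closed in age powers"
                )
            T[i, j] = comb(p, q) * (-c) ** (p - q) / s**p
    return T
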