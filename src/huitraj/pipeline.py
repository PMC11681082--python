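"""End-to-end pipeline: simulate -> fit -> weight -> QALY.

``run_pipeline`` sequences the synthetic cohort generator (or a user
panel), AIC covariate retention, survey-bootstrap variance, the attrition
sensitivity fits, and the QALY contrast, writing each stage's table to the
output directory with provenance metadata (config hash, seed, package
versions).  ``scenario_suite`` tabulates the NO2 coefficients across the
standard sensitivity variants side by side.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, presets
from .attrition import AttritionModel, compute_ip_weights, weighted_refit
from .cohort import (CohortConfig, ExposureParams, completion_summary,
                     generate_bootstrap_weights, generate_cohort)
from .growth import GrowthCurveModel, aic_retention, bootstrap_vcov
from .qaly import Scenario, delta_qaly, monte_carlo_uncertainty, predict_trajectory

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "scenario_suite"]

#: Candidate covariates in adjustment-set order (sex, income, education,
#: racialized group, physical activity) followed by smoking.
DEFAULT_CANDIDATES = ("female", "income_ratio", "less_than_hs", "indigenous",
                      "active", "smoker")


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    seed: int = 0
    n_participants: int = 2000
    n_replicates: int = 50
    outdir: str | Path = "huitraj_run"
    cohort: dict = field(default_factory=dict)
    model: dict = field(default_factory=lambda: {
        "outcome": "raw_hui", "exposure_form": "continuous",
        "exposure_window": "period_mean"})
    candidates: tuple = DEFAULT_CANDIDATES
    aic_selection: bool = True
    scenarios: dict = field(default_factory=lambda: {
        "reference_no2_ppb": presets.BACKGROUND_NO2_PPB,
        "alternative_no2_ppb": presets.MEAN_NO2_PPB,
        "covariate_profile": {"female": 1.0, "income_ratio": 2.2,
                              "less_than_hs": 0.0, "indigenous": 0.0,
                              "smoker": 0.0, "active": 0.0}})
    qaly: dict = field(default_factory=lambda: {
        "age_ranges": [[20, 80], [20, 100]],
        "methods": ["spline", "trapezoid", "step"],
        "n_iter": 200})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def cohort_config(self) -> CohortConfig:
        kw = dict(self.cohort)
        expo = kw.pop("exposure_params", None)
        cfg = CohortConfig(n_participants=self.n_participants, seed=self.seed,
                           **kw)
        if expo:
            cfg.exposure_params = ExposureParams(**expo)
        return cfg

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, Path):
                return str(o)
            raise TypeError(type(o).__name__)
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    coefficients: pd.DataFrame
    retention_log: pd.DataFrame
    attrition_tables: dict[str, pd.DataFrame]
    qaly_report: pd.DataFrame
    cohort_summary: dict
    metadata: dict
    outdir: Path


def _write(df: pd.DataFrame, outdir: Path, name: str):
    path = outdir / name
    df.to_csv(path, index=False)
    log.info("pipeline stage output: %s (%d rows, sha %s)", path, len(df),
             hashlib.sha256(path.read_bytes()).hexdigest()[:12])


def run_pipeline(config: RunConfig, panel: pd.DataFrame | None = None) -> ReportBundle:
    """Run all stages; idempotent per seed.

    A user panel can replace the synthetic cohort stage.  Stage failures
    propagate with the stage name; outputs written before the failure are
    preserved in ``outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if panel is None:
            cohort_cfg = config.cohort_config()
            panel = generate_cohort(cohort_cfg)
            _write(panel, outdir, "panel.csv")
        summary = completion_summary(panel)

        stage = "weights"
        ids = np.sort(panel["participant_id"].unique())
        reps = generate_bootstrap_weights(
            ids, config.n_replicates,
            seed=panel.attrs.get("weight_seed", config.seed + 1))
        reps.reset_index().to_csv(outdir / "replicate_weights.csv", index=False)

        stage = "fit"
        base = GrowthCurveModel(**config.model)
        if config.aic_selection:
            model, retention = aic_retention(panel, base, config.candidates)
        else:
            model = base.fit(panel)
            retention = pd.DataFrame(
                columns=["candidate", "aic_without", "aic_with", "retained",
                         "note"])
        _write(retention, outdir, "retention_log.csv")

        stage = "bootstrap"
        model.vcov_ = bootstrap_vcov(panel, model, reps)
        coef = model.coefficient_table()
        _write(coef, outdir, "coefficients.csv")

        stage = "attrition"
        attrition_tables = {}
        for outcome in ("completed_all_cycles", "survived"):
            am = AttritionModel(outcome=outcome,
                                exposure_window=model.exposure_window).fit(panel)
            ipw = compute_ip_weights(am, panel)
            refit = weighted_refit(panel, model, ipw)
            tab = refit.coefficient_table()
            tab.insert(0, "weighting", f"ip_{outcome}")
            attrition_tables[outcome] = am.coefficient_table()
            _write(am.coefficient_table(), outdir, f"attrition_{outcome}.csv")
            _write(tab, outdir, f"refit_ip_{outcome}.csv")
            ipw.rename("weight").reset_index().rename(
                columns={"index": "participant_id"}).to_csv(
                outdir / f"ip_weights_{outcome}.csv", index=False)

        stage = "qaly"
        qrecords = []
        if model.exposure_form == "none":
            log.info("qaly stage skipped: model has no exposure term")
            qdf = pd.DataFrame(
                columns=["age_lo", "age_hi", "method", "qaly_ref", "qaly_alt",
                         "absolute", "percent", "ci_low", "ci_high", "p_value"])
        else:
            sc = config.scenarios
            ref = Scenario(sc["reference_no2_ppb"], sc["covariate_profile"],
                           "reference")
            alt = Scenario(sc["alternative_no2_ppb"], sc["covariate_profile"],
                           "alternative")
            for lo, hi in config.qaly["age_ranges"]:
                for method in config.qaly["methods"]:
                    d = delta_qaly(model, ref, alt, (lo, hi), method)
                    mc = monte_carlo_uncertainty(
                        model, ref, alt, (lo, hi), method,
                        n_iter=config.qaly["n_iter"], seed=config.seed + 97)
                    qrecords.append({"age_lo": lo, "age_hi": hi,
                                     "method": method, **d,
                                     "ci_low": mc["ci_low"],
                                     "ci_high": mc["ci_high"],
                                     "p_value": mc["p_value"]})
                curve = predict_trajectory(model, ref, lo, hi)
                pd.DataFrame({"age": curve.ages, "hui": curve.values}).to_csv(
                    outdir / f"trajectory_ref_{lo}_{hi}.csv", index=False)
            qdf = pd.DataFrame(qrecords)
        _write(qdf, outdir, "qaly_report.csv")

        metadata = {
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "huitraj_version": __version__,
            "numpy_version": np.__version__,
            "pandas_version": pd.__version__,
            "n_participants": int(panel["participant_id"].nunique()),
            "cohort_summary": summary,
        }
        (outdir / "metadata.json").write_text(json.dumps(metadata, indent=2))
        return ReportBundle(coefficients=coef, retention_log=retention,
                            attrition_tables=attrition_tables, qaly_report=qdf,
                            cohort_summary=summary, metadata=metadata,
                            outdir=outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def scenario_suite(panel: pd.DataFrame, model: GrowthCurveModel) -> pd.DataFrame:
    """Sensitivity-variant comparison of the NO2 coefficient block.

    Variants: primary fit, cycle-1 exposure window, complete-case
    restriction, non-mover restriction, arcsine outcome, and IPW refits
    (completion; survival).  An empty variant analysis set is skipped with
    a logged reason.  Returns one row per variant with the NO2 main effect
    and its age interactions.
    """
    variants: list[tuple[str, callable]] = []

    def fit_with(**overrides):
        m = GrowthCurveModel(**model.get_params())
        for k, v in overrides.items():
            setattr(m, k, v)
        return m

    variants.append(("primary", lambda: fit_with().fit(panel)))
    variants.append(("cycle1_window",
                     lambda: fit_with(exposure_window="cycle1").fit(panel)))

    def complete_case():
        last = panel["cycle"].max()
        done = panel.loc[(panel["cycle"] == last) & panel["alive"]
                         & panel["responded"], "participant_id"]
        sub = panel[panel["participant_id"].isin(done)]
        return fit_with().fit(sub)

    def non_movers():
        n_res = panel.groupby("participant_id")["residence_id"].nunique()
        stay = n_res[n_res == 1].index
        sub = panel[panel["participant_id"].isin(stay)]
        return fit_with().fit(sub)

    variants.append(("complete_case", complete_case))
    variants.append(("same_residence", non_movers))
    variants.append(("arcsine_outcome",
                     lambda: fit_with(outcome="arcsine_hui").fit(panel)))

    def ipw(outcome):
        am = AttritionModel(outcome=outcome,
                            exposure_window=model.exposure_window).fit(panel)
        return weighted_refit(panel, model, compute_ip_weights(am, panel))

    variants.append(("ip_completion", lambda: ipw("completed_all_cycles")))
    variants.append(("ip_survival", lambda: ipw("survived")))

    rows = []
    for name, fn in variants:
        try:
            m = fn()
        except ValueError as exc:
            log.warning("scenario_suite: variant %s skipped (%s)", name, exc)
            continue
        beta = m.beta_
        rows.append({"variant": name,
                     "no2": beta.get("no2", np.nan),
                     "no2:age": beta.get("no2:age", np.nan),
                     "no2:age^2": beta.get("no2:age^2", np.nan),
                     "aic": m.aic_, "n_obs": m.n_obs_})
    return pd.DataFrame(rows)
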