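# huitraj

Random growth-curve modelling of Health Utilities Index (HUI) trajectories
under long-term NO₂ exposure, with survey-bootstrap variance,
inverse-probability-of-attrition weighting, and QALY quantification — plus
a calibrated synthetic cohort generator emulating a nine-cycle biennial
Canadian population health panel (an NPHS-like design).

## Who this is for

Environmental epidemiologists and health economists who want to model how
a global health-related quality-of-life measure evolves with age in
relation to an environmental exposure, and to translate fitted
trajectories into quality-adjusted life years (QALYs) at the person and
population level.  Because the microdata such analyses rely on are
typically restricted, the package ships a first-class synthetic cohort
generator with known ground truth, so the entire pipeline is testable and
demonstrable without access to confidential data.

## The model

HUI for participant *i* is modelled as a cubic polynomial of age with
exposure and covariate blocks, each block interacting with powers of age:

```
HUI_i = β₀ + β₁·age_i + β₂·age_i² + β₃·age_i³
        + Σ_j β_j·x_j + Σ_j (β_k·age_i·x_j + β_l·age_i²·x_j + β_m·age_i³·x_j)
        + b₀ᵢ + b₁ᵢ·age_i + ε
```

where `x_j` includes NO₂ (ppb) and socio-demographic covariates, and
`(b₀ᵢ, b₁ᵢ)` are participant-level random intercepts and age slopes
(a random growth-curve model).  Estimation is weighted maximum likelihood,
so the same fitter serves unweighted fits, survey bootstrap replicate
weights, and inverse-probability-of-attrition weights.  Covariates are
retained when they reduce the AIC; a variance-stabilising arcsine
transform of HUI, `arcsin(2·(HUI + 0.36)/1.36 − 1)`, is available as a
sensitivity outcome.  QALYs between two ages are the area under the
HUI-by-age curve (spline, trapezoid or step rule); population totals scale
per-person differences by an age pyramid and life-table survival, and
uncertainty is propagated by Monte-Carlo sampling of the NO₂ coefficient
block.

## Worked example

```python
import numpy as np
import huitraj as ht

cfg = ht.CohortConfig(n_participants=2000, seed=1)
panel = ht.generate_cohort(cfg)
print(ht.completion_summary(panel))
# {'n': 2000, 'pct_died': 15.55, 'pct_completed': 45.2, 'pct_dropped_alive': 39.25}

model = ht.GrowthCurveModel(exposure_form="continuous").fit(panel)
ids = np.sort(panel["participant_id"].unique())
reps = ht.generate_bootstrap_weights(ids, 100, seed=panel.attrs["weight_seed"])
model.vcov_ = ht.bootstrap_vcov(panel, model, reps)   # design-based variance
print(model.coefficient_table().round(6).to_string(index=False))
#      term  estimate       se  p_value
# Intercept  1.258962 0.034620 0.000000
#       age -0.023637 0.002023 0.000000
#     age^2  0.000553 0.000039 0.000000
#     age^3 -0.000004 0.000000 0.000000
#       no2 -0.005773 0.001505 0.000125
#   no2:age  0.000245 0.000061 0.000064
# no2:age^2 -0.000002 0.000001 0.000078

ref = ht.Scenario(0.15, label="background")     # natural background NO2, ppb
alt = ht.Scenario(12.7, label="sample mean")
print(ht.delta_qaly(model, ref, alt, (20, 80), "spline"))
# {'qaly_ref': 54.569, 'qaly_alt': 54.225, 'absolute': 0.344, 'percent': 0.63}

mc = ht.monte_carlo_uncertainty(model, ref, alt, (20, 80), "spline",
                                n_iter=1000, seed=1)
# 95% CI (-0.065, 0.741), p = 0.116
```

Reading the numbers: the cohort loses ~15.6% of participants to death and
~44% to non-response over nine cycles, matching its calibration targets.
The fitted NO₂ main effect is negative (worse HUI at higher exposure) with
a positive linear-age and negative quadratic-age interaction, so the
trajectory gap widens in later life.  Holding covariates fixed, a person
at the background concentration (0.15 ppb) accrues 0.344 QALYs more
between ages 20 and 80 than one at the sample-mean concentration
(12.7 ppb) — a 0.6% difference whose Monte-Carlo interval includes zero.

The same stages are scriptable from a shell:

```sh
huitraj simulate --n 2000 --seed 1 --out panel.csv
huitraj fit --panel panel.csv --out coefficients.csv
huitraj attrition --panel panel.csv --outcome completed_all_cycles
huitraj run --seed 1 --outdir run1     # full pipeline with report files
```

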