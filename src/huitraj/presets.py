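"""Reference fixed-effect coefficient profiles for HUI-by-age trajectories.

These coefficient sets describe a cubic polynomial trajectory of the Health
Utilities Index (HUI) by age, optionally with a continuous NO2 exposure term
and its interactions with linear and quadratic age, and with the standard
socio-demographic covariates used in Canadian national population health
cohort analyses.  Units: HUI utility per unit of each regressor (age in
years, NO2 in ppb, indicators 0/1, income ratio in multiples of the low
income cut-off).

They serve two purposes:

* ground truth for the synthetic cohort generator, so simulated panels have
  realistic age trajectories and exposure effects, and
* ready-made fixed-effects models for the QALY module's worked examples
  (trajectory prediction and area-under-curve contrasts) without refitting.

Published trajectory analyses report covariate coefficients but not the
model intercept; ``DEFAULT_INTERCEPT`` is calibrated so that the generated
cycle-1 HUI mean is ~0.9 under the default generator settings.
"""

from __future__ import annotations

# Cubic age polynomial alone.
AGE_ONLY_EFFECTS: dict[str, float] = {
    "age": -2.08e-02,
    "age^2": 5.28e-04,
    "age^3": -4.42e-06,
}

# Age polynomial plus continuous NO2 with age and age^2 interactions.
BASE_NO2_EFFECTS: dict[str, float] = {
    "age": -2.26e-02,
    "age^2": 5.48e-04,
    "age^3": -4.41e-06,
    "no2": -3.44e-03,
    "no2:age": 1.70e-04,
    "no2:age^2": -1.88e-06,
}

# Fully adjusted profile: NO2 plus sex, income, education, Indigenous
# identity and smoking, each with polynomial age interactions.
ADJUSTED_EFFECTS: dict[str, float] = {
    "age": -2.49e-02,
    "age^2": 6.03e-04,
    "age^3": -4.77e-06,
    "no2": -2.85e-03,
    "no2:age": 1.52e-04,
    "no2:age^2": -1.76e-06,
    "female": 4.74e-02,
    "female:age": -1.83e-03,
    "female:age^2": 2.43e-05,
    "female:age^3": -1.41e-07,
    "income_ratio": -4.59e-02,
    "income_ratio:age": 4.12e-03,
    "income_ratio:age^2": -9.08e-05,
    "income_ratio:age^3": 6.71e-07,
    "less_than_hs": 3.95e-01,
    "less_than_hs:age": -2.78e-02,
    "less_than_hs:age^2": 5.65e-04,
    "less_than_hs:age^3": -3.49e-06,
    "indigenous": -2.59e-01,
    "indigenous:age": 1.01e-02,
    "indigenous:age^2": -1.08e-04,
    "smoker": -3.11e-01,
    "smoker:age": 2.21e-02,
    "smoker:age^2": -4.95e-04,
    "smoker:age^3": 3.19e-06,
}

#: Sample-mean NO2 concentration (ppb) in the emulated cohort.
MEAN_NO2_PPB = 12.7
#: Estimated natural background NO2 concentration (ppb).
BACKGROUND_NO2_PPB = 0.15

#: Generator intercept calibrated so cycle-1 HUI mean ~ 0.9 at defaults
#: (set by the calibration described in docs/methods.md).
DEFAULT_INTERCEPT = 1.3251
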