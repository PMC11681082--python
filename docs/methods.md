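# Methods

## The trajectory model

The outcome is the Health Utilities Index (HUI), a multi-attribute
utility score on [−0.36, 1] where 1 is perfect health, 0 is death and
negative values are states rated worse than death.  We model HUI as a
cubic polynomial in age with exposure and covariate blocks; each block is
a main effect plus products with powers of age (up to age³, with the NO₂
and Indigenous-identity blocks limited to age² — the layout in which such
models are conventionally reported).  Participants enter as random
effects: by default a random intercept and a random linear-age slope with
an unstructured 2×2 covariance (an intercept-only structure is available
for hard-to-fit data).

Fitting maximises the marginal Gaussian likelihood.  Three choices
matter:

* **Weighted likelihood.**  Each participant's marginal log-likelihood
  contribution can be multiplied by a participant weight.  This one
  mechanism serves survey design weights, bootstrap replicate weights and
  inverse-probability-of-attrition weights; constant weights reproduce
  the unweighted fit exactly (tested).  The likelihood is authored
  in-package (`_lmm.py`) because the established mixed-model fitters do
  not expose participant-level weights on the marginal likelihood; the
  unweighted fit is cross-checked against `statsmodels` `MixedLM` in the
  test suite (log-likelihood agreement to ~1e−4 relative).
* **ML, not REML**, so AIC comparisons across fixed-effect
  specifications (covariate retention, continuous vs. quartile exposure)
  are valid.  AIC = −2·loglik + 2·(fixed effects + variance components).
* **Internal age standardisation.**  Cubic terms in raw years are
  numerically ill-conditioned, so the fitter works with a = (age − 50)/10
  and maps coefficients and covariances back to raw-year units by the
  exact binomial-expansion linear map.  Reported coefficients are always
  on the raw-age scale.

The optimiser profiles out the fixed effects (weighted GLS) and the
residual variance in closed form and runs L-BFGS-B over the log-Cholesky
factor of the scaled random-effect covariance (1 or 3 parameters), with
participants batched by observation count so the linear algebra is fully
vectorised.  A near-exact fit (profiled residual variance below 1e−12,
e.g. noise-free synthetic data) short-circuits the optimisation, since
the fixed effects are then invariant to the variance parameters and the
profiled objective is dominated by floating-point cancellation.
Convergence failures raise an error carrying the optimiser diagnostics;
a line-search stall that made no progress from a usable start is accepted
with the start value.

Model-based coefficient covariance is σ̂²(Σᵢ wᵢ XᵢᵀKᵢ⁻¹Xᵢ)⁻¹.  P-values in
coefficient tables use a normal reference and are labelled as such.

### Survey bootstrap variance

Design-based variance uses replicate weights: the model is refit under
each replicate column and the covariance of replicate estimates around
the main-weight estimate, (1/B)Σ(β_b − β̂)(β_b − β̂)ᵀ, replaces the
model-based covariance.  Replicate weights are generated by rescaled
with-replacement resampling (weight × multinomial count, rescaled to the
main-weight mean), the standard construction for household-survey
replicate weights.  By default the replicate refits re-solve the weighted
GLS fixed effects at the main-fit variance parameters; this exploits the
asymptotic orthogonality of fixed effects and variance components in the
Gaussian mixed model and reduces each replicate to a weighted sum of
precomputed per-participant moment matrices (hundreds of replicates per
second).  Full per-replicate re-optimisation is available via
`reestimate_variance=True`.  More than 10% non-converging replicates is
an error; fewer are dropped with a warning.

### Covariate retention and exposure form

`aic_retention` adds candidates in a fixed order — the causal
adjustment-set order (sex, income, education, racialized group, physical
activity) followed by smoking — and keeps a candidate (main effect plus
its age-interaction block) iff the AIC strictly decreases.  The quartile
exposure specification replaces continuous NO₂ with Q2–Q4 indicators (Q1
reference), each with main effect and age, age² interactions; quartile
cutpoints use averaged-inverted-CDF sample quantiles (the inverse
empirical CDF with averaging at discontinuities; exposures 1..8 give cuts
2.5/4.5/6.5), computed from one value per participant.  The quartile fit
reports its AIC next to the continuous fit's so the shape of the
concentration–response relationship can be judged.

### Missing covariate categories

Categorical covariates carry explicit `"missing"` levels at realistic
rates.  The default policy represents missingness as its own indicator
column (main effect only); listwise deletion is a configuration switch.
The choice is a modelling convention, not an imputation method.

## Attrition and inverse probability weighting

Nine-cycle summary outcomes — survival to the last cycle and completion
of all cycles — are modelled by logistic regression on the same variables
as the HUI model (age and NO₂ enter linearly; exposure summarised as the
period mean by default, cycle-1 optionally).  IP weights are 1/p̂ for the
participants with the outcome, optionally truncated at symmetric
percentiles, then normalised to mean 1; the weighted refit runs the
growth-curve model on those participants with the IP weights (optionally
multiplied by design weights — the two are never combined by default,
and survival and completion weighting are always separate analyses).
Apparent complete separation (|coefficient| > 50) is an error naming the
predictor.

What IPW can and cannot fix here is demonstrated honestly in the test
suite: when dropout targets participants whose exposure response is
steepest (old age) through variables that are in the weight model,
complete-case restriction attenuates the NO₂ coefficient and IP-completion
weighting pulls it back toward the no-attrition population estimand.
When dropout depends on outcome history (the generator's default,
realistic mode), likelihood-based fits on the full panel remain valid
under MAR, while complete-case restriction is biased — and a weight model
restricted to baseline covariates can only partially correct it.

## QALY quantification

One year at utility u contributes u QALYs, so per-person QALYs between
two ages are the area under the predicted HUI-by-age curve on a unit age
grid (61 points for 20–80, 81 for 20–100).  Three integration rules are
provided: composite trapezoid; left-value step rectangles (which
over-count decreasing curves, so step ≥ trapezoid there — tested); and a
cubic interpolating spline integrated in closed form.  The spline's
default boundary condition is not-a-knot, which reproduces single cubic
polynomials exactly (the property the tests pin down, and the behaviour
of the classic Forsythe–Malcolm–Moler spline interpolator); a natural
boundary condition is available.  Models fitted on the arcsine scale are
back-transformed to utilities before integration — a plug-in choice with
no Jacobian correction, since QALYs are defined on the utility scale.
Predicted values are clipped to [−0.36, 1] (clips logged); clipping to
[0, 1] before integration is off by default.

Population totals: for each baseline-age cohort in the supplied age
pyramid, the per-year HUI difference is summed over future ages from
max(20, a) to the horizon (80 or 100), weighted by life-table conditional
survival S(y)/S(a) and the cohort count.  Both endpoint ages count as
lived years ("inclusive" convention; an exclusive-horizon variant is a
switch).  Cohorts younger than 20 are excluded by default.  The
accounting is deliberately conservative: only the baseline population
ages through the horizon, with no births or immigration.

Uncertainty: the NO₂-related coefficient block (optionally the full
vector) is drawn from a multivariate normal with the model's coefficient
covariance (the bootstrap covariance when attached), the QALY contrast is
recomputed per draw, and the 95% percentile interval is reported with an
add-one-corrected two-sided Monte-Carlo p-value,
min(1, 2·min(#(Δ≤0)+1, #(Δ≥0)+1)/(n_iter+1)).  The default 1,000
iterations take well under a second.

## The synthetic cohort generator

The generator emulates a nine-cycle biennial national health panel with
known ground truth.  Defaults are calibrated once to the published
characteristics of such a cohort and then frozen:

* **Ages**: truncated normal (minimum 20, cap 95) whose truncated moments
  match mean 46.5 / SD 17.7.
* **Covariates**: categorical marginals at published rates (54% female;
  24.3% less than high school; 1.1% Indigenous; 24% daily smokers; etc.),
  with explicit missing categories; income ratio as a moment-matched
  gamma (mean 2.2, SD 1.3).  Covariates are fixed at their baseline
  values across cycles.
* **Exposure**: each participant has a long-run NO₂ level (lognormal,
  floored at the 0.15 ppb natural background); residences (1–4 per the
  published postal-code-count distribution, change cycles uniform) redraw
  a mean-one spatial factor composed of lognormal noise (CV 0.26) and a
  near-road gradient (1.65× at highways decaying linearly to 1 at 300 m;
  1.2× at major roads to 1 at 100 m; class mix 3/12/85%); cycles within a
  residence share the spatial factor times mean-one temporal scaling
  noise (CV 0.14).  The lognormal parameters are moment-matched so the
  distribution of participant period means has mean 12.7 / SD 7.6 ppb,
  and the two noise CVs are calibrated so Spearman(cycle-1, period mean)
  ≈ 0.92.
* **HUI**: the growth-curve mean (default coefficients: the
  age-plus-NO₂ profile above with intercept 1.3251, calibrated so the
  cycle-1 HUI mean is 0.90) plus random intercept (SD 0.16), random age
  slope (SD 0.002/year) and residual noise (SD 0.11), truncated to
  [−0.36, 1].  The truncation emulates the strong ceiling of real HUI
  data and is reported as a fraction.
* **Attrition**: two per-cycle logistic continuation processes (death
  absorbing and blocking response; dropout absorbing).  Continuation
  log-odds fall with age (−0.092/year for survival), NO₂ (−0.012/ppb),
  smoking and Indigenous identity, rise with female sex, income and
  previous-cycle HUI (making attrition informative), matching the
  directions reported for such cohorts.  Intercepts (6.05 survival, 2.46
  response) are calibrated so ~15.6% die and ~43.9% complete all nine
  cycles at n = 20,000.

What passing tests do and do not show: the generator's realism is
statistical, not spatial — there are no coordinates, no actual LUR
surface, and no within-person covariate dynamics; exposure–covariate
correlations are zero by default.  Results on synthetic data demonstrate
that the estimation machinery is correct under the stated data-generating
process, not that any particular real-world effect estimate is right.

### Ceiling censoring and the machinery tests

At the default calibration the HUI mean (0.90) sits close to the ceiling
(1.0) relative to the noise SD, so a large share of young participants'
raw values are censored at 1 — as in real HUI data.  Censoring makes the
linear-model coefficients differ from the generator's (the censored mean
is not the linear predictor), which is a property of the measure, not an
estimation defect.  Checks of the fitting machinery itself (parameter
recovery, interval coverage, AIC ordering, Monte-Carlo test calibration)
therefore run on configurations whose trajectories stay strictly inside
the utility range: baseline ages capped at 60, intercept 0.8, random
intercept SD 0.12, residual SD 0.09 — zero truncation.  Calibration
checks (exposure moments, HUI mean, death fraction, exposure
autocorrelation) run at full defaults.

## Simulation sizes and statistical bands in the test suite

Heavy checks are sized for a serial run while keeping their stated bands:
parameter recovery, 50 replicate cohorts of n = 2,000 (mean estimate
within 2 Monte-Carlo SEs of truth for the NO₂ main effect and age
interaction); bootstrap interval coverage, 140 cohorts of n = 1,000 at
B = 50 (95% ± 4%); continuous-vs-quartile AIC ordering, 30 cohorts
(≥ 90% wins); Monte-Carlo type-I error, 300 null cohorts of n = 800 at
200 draws (5% ± 2%); attrition-direction checks, 8 cohorts of n = 5,000
against a no-attrition estimand fitted at n = 15,000.

## Known limitations

* Linear mixed model only: no non-linear links, spatial random effects,
  multiple imputation, or time-varying (cumulative-product) IPW.
* The weighted-likelihood covariance is model-based between bootstrap
  calls; pseudo-likelihood sandwich corrections are not implemented —
  design-based inference should use `bootstrap_vcov`.
* At small samples (a few hundred participants) with heavy dropout, the
  model-based and bootstrap SEs for participant-level covariates run a
  few percent anti-conservative; coverage is nominal from roughly 1,000
  participants.
* The generator draws covariates independently of exposure; confounding
  scenarios must be constructed explicitly (the test suite shows how).
* Percent QALY changes are undefined when the reference QALY total is
  zero (flagged, returned as NaN).
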