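# Methods

This note documents the statistical model, the synthetic-data mechanism,
the numerical choices, and the places where the design was genuinely
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The model

The target of inference is a patient's absolute risk of a colorectal
cancer diagnosis within two years of their most recent full blood count
(the *baseline* FBC). Models are fitted separately by sex.

### Study clock and cohort preparation

The baseline FBC anchors two windows: a five-year *longitudinal* window
ending at baseline (window time `t ∈ [0, 5]`, baseline at `t = 5`), and
a two-year *prediction* horizon after it. Preparation enforces the
design:

- measurements outside configurable plausible ranges are dropped
  (defaults: HB 3–25 g/dL, MCV 50–150 fL, PLT 10–1500 ×10⁹/L);
- measurements dated less than 21 months (24 − 3) before the
  diagnosis/censor date are excluded, and the baseline is re-derived as
  the most recent *surviving* measurement. This guarantees every
  retained patient at least 21 months of event-free follow-up after
  baseline and keeps the predictors at least ~2 years away from
  diagnosis;
- a diagnosis up to 27 months (24 + 3) after baseline counts as an
  event; later or absent diagnoses are censored at the earliest exit,
  capped at 2 years. The asymmetric 21/27 pairing is the only reading
  of a "two years ± three months" outcome under which a case's recent
  FBCs are all excluded while the case itself remains ascertainable;
- eligibility: age ≥ 40 at baseline, ≥ 1 retained measurement of each
  analyte, ≥ 1 year registered before baseline. Dates are handled in
  days and converted with 365.25 d/y; same-day duplicates of one
  analyte are averaged (deterministic tie-break).

### Longitudinal sub-models

One linear mixed model per analyte (HB, MCV, PLT), fitted to all
retained patients jointly:

    y_ij = β₀ + f_age(age_i) + f_time(t_ij) [+ δ age_i t_ij]
           + b0_i + b1_i t_ij + ε_ij,
    (b0, b1) ~ N(0, G) unstructured,  ε ~ N(0, σ²)

`f_age`, `f_time` are linear splines, basis `[x, (x−k)₊ …]`, with age
knots 60/70/80 (HB), 55 (MCV), 60 (PLT) and a time knot at year 3; age
is age at baseline, constant within patient, entering untransformed in
the HB age×time interaction. Analytes are fitted independently (a
block-diagonal approximation to a six-random-effect multivariate fit);
the downstream architecture needs only per-analyte deviations, and
cross-analyte random-effect correlation is weak in this setting.

Estimation is REML. With only two random effects the restricted
likelihood reduces to per-patient cross-products (`Z'Z`, `Z'X`, `Z'y`
with `z = (1, t)`), so one evaluation of the profiled criterion — β and
σ² concentrated out, leaving the 3 free parameters of the Cholesky
factor of `D = G/σ²` — costs a handful of elementwise passes over
patients plus four p×p GEMMs. The optimiser is Nelder–Mead started from
a method-of-moments estimate (per-patient OLS random-effect estimates,
noise-corrected; only patients with ≥ 3 measurements and a reasonable
time spread contribute, because the noise correction involves
`(Z'Z)⁻¹`, which explodes for clustered visit times). Two safeguards
address observed failure modes of this surface: a fresh-simplex restart
when the first pass exhausts its budget (Nelder–Mead's terminal
convergence is slow), and a retry from an inflated-slope start when the
fitted slope variance collapses far below its start (the profiled
surface can hold a spurious local minimum with near-zero slope
variance). Simplex tolerances are 1e-6 on parameters and 1e-8 on the
criterion — the criterion's own floating-point noise floor is ≈1e-8 at
10⁵ observations, which is why the response is mean-centred before the
cross-products are formed. The fit is deterministic: fixed start, no
random restarts, bitwise-reproducible.

### From trajectories to hazard

For each patient and analyte the random effects are predicted by their
conditional mean (BLUP) given the patient's residuals,
`b = G (Z'Z G + σ²I)⁻¹ Z'r` (a form valid for singular `G`), and
summarised as the **trend deviation** `d = b0 + 5·b1`: the value-scale
gap between the patient's own trajectory and the population curve *at
the baseline time*. The deviation — not the slope — is used because the
hazard ratios are then per analyte unit (g/dL, fL, 10⁹/L), which is the
interpretable scale for a screening model. Patients with no
measurements of an analyte fall back to the population mean (`d = 0`)
with a logged warning; no imputation is performed.

Because the BLUP is a conditional expectation, the error `d − d̂` is
independent of `d̂` (Berkson structure); for a rare-event Cox model this
leaves the deviation hazard ratios essentially unbiased despite the
strong shrinkage at 3–4 measurements per patient. This is what makes
the two-stage estimator (mixed fits → BLUPs → Cox) a faithful stand-in
for simultaneous joint maximisation, which at 50,000+ patients and six
random effects per patient is not a desk-scale computation. The
two-stage choice is the headline methodological approximation of this
package.

### Cox sub-model and absolute risk

The Cox model has five covariates: the repeated-power-2 fractional
polynomial age pair `(a², a² log a)`, `a = age/age_scale`, plus the
three deviations. `age_scale` defaults to 1; see "Open choices". The
partial likelihood uses Breslow tie handling (ties arise from day-level
date resolution), maximised by Newton–Raphson with step halving from
β = 0 on covariates centred at their cohort means; standard errors come
from the inverse observed information, CIs as `exp(β ± 1.96·SE)`.
Constant covariates are dropped from the iteration and reported as
coefficient 0. The Breslow baseline cumulative hazard at the centred
predictors gives `S₀(2) = exp(−H₀(2))`; with null covariates this
reduces exactly to the Nelson–Aalen estimator (tested). Absolute risk
is `1 − S₀(2)^exp(lp)`, strictly increasing in the linear predictor.

Prediction is dynamic: `predict_patient` re-anchors the five-year
window at the newest FBC in the supplied history, recomputes BLUPs and
deviations, and returns the updated risk; appending a new measurement
and re-calling yields the new risk.

## Synthetic cohorts

The generator's role is to produce cohorts with exactly the statistical
structure the analysis assumes — the joint model *is* the generative
mechanism — so that parameter recovery is a well-posed check of the
pipeline. Per patient: age from a truncated normal (males 60.7, SD
13.0, range 40–104; females 61.9, SD 14.6, 40–108 — the non-case
moments of the target population); a baseline FBC panel at `t = 5` plus
Poisson-many historic panels uniform on `[0, 5)` (mean 3.2 panels per
patient, matching ~0.8M measurements per 250k patients; 3% per-analyte
missingness); random effects from the configured `G` per analyte;
values from the mixed-model mean plus residual noise.

Event times come from the Cox sub-model by inverse transform:
`T = 1.75 + Exp(h₀·m·exp(lp − mean lp))` — a constant (exponential)
baseline hazard shifted by the 21-month follow-up guarantee that the
exclusion window enforces in prepared data. Proportional hazards are
invariant to the shift, so the configured log-hazard coefficients
remain the estimands. Two generator-level choices matter:

- **Events are ascertained within the two-year horizon.** Recording
  diagnoses in the (24, 27]-month tail while censoring non-cases at 24
  months would make censoring informative (risk sets past the cap would
  contain only future cases) — negligible at a 0.3% event rate, but it
  visibly attenuates coefficients at the 10× inflated rates used for
  desk-scale fits. The 27-month coding rule therefore lives in cohort
  preparation, where it is a data rule, not in the hazard.
- **Baseline hazards** default to 0.0084/y (male) and 0.0078/y
  (female), calibrated once so the default truth yields the target
  ~0.4%/0.3% two-year event rates at multiplier 1. Recovery tests use
  `event_rate_multiplier = 10` — covariate hazard ratios are invariant
  to baseline-rate scaling, and 0.3% of a desk-scale cohort is too few
  events for a stable five-covariate Cox fit.

Coefficient truth defaults are the published sex-specific hazard
ratios: age² 1.015/1.014, age²·log(age) 0.997/0.99717, HB 0.868/0.863
per g/dL, MCV 0.996/0.986 per fL, PLT 1.001/1.002 per 10⁹/L. The
female age²·log(age) default carries a fourth digit: at three digits
the two female age terms cancel to a flat age–hazard gradient, which
contradicts the ~10-year case/non-case age gap of the target
population; 0.99717 restores the gradient and still rounds to 0.997.
Trajectory truths (intercepts ~15.4/14.4 g/dL HB, ~86 fL MCV, ~280/305
×10⁹/L PLT, gentle age/time slopes, between-patient SDs ~0.95 g/dL /
3.2 fL / 48 ×10⁹/L) are configuration chosen to be realistic for UK
primary care, not estimates from any restricted dataset.

What the generator deliberately does **not** emulate: comorbidity
confounding (in real data, frequent testing correlates with illness),
practice-level clustering, analyte-specific pre-diagnosis trend shapes
beyond what the linear random-slope model encodes, and
measurement-batch effects. Passing tests therefore demonstrate that the
pipeline recovers the model's own truth and that the metric
implementations are correct — not that the model is well-specified for
real cohorts.

## Validation metrics

- **Brier score** at 2 years with IPCW: weights `1/G(T−)` for events
  before the horizon, `1/G(2−)` for survivors, 0 for earlier censorings,
  `G` the Kaplan–Meier of the censoring distribution. Reduces to the
  plain MSE without censoring.
- **Harrell's c** over usable pairs (lifelines implementation; tied
  predictions get half credit), CI from the Hanley–McNeil variance
  approximation with event/non-event counts.
- **Royston–Sauerbrei D**: Blom scores `Φ⁻¹((r−3/8)/(n+1/4))` of the
  prognostic index, divided by κ = √(8/π), Cox-regressed on survival;
  D is the coefficient, CI from its SE. Blom's approximation to exact
  normal order statistics is accurate well below the reported precision
  for n ≥ 20. All-tied indices give D = 0 by convention.
  `R²_D = (D²/κ²)/(π²/6 + D²/κ²)`.
- **Calibration slope**: Cox coefficient of the PI on evaluation data;
  exactly 1 on the development data by the score equation (tested to
  1e-6).
- **Calibration bins**: 20 equal-count groups of predicted risk; per
  bin, mean predicted risk vs `1 − KM(2)`.
- **Subgroups**: the same report per 10-year age band (40–90, then
  90+), per FBC count, and per 6-month band of FBC time span; sparse
  subgroups are flagged rather than suppressed.

Threshold analysis uses type-1 (inverse-ECDF) empirical quantiles of
predicted risk; "positive" is *strictly above* the cut-off, so with
distinct risks the flagged fraction at percentile p is exactly
(100 − p)%. Censored-before-horizon patients count as negatives so the
confusion margins always total the cohort. Accuracy percentages are
rounded half-up to two decimals. Percentile thresholds are computed on
the cohort being evaluated.

## Open choices

- **FP age scaling.** The published age hazard ratios do not pin down
  the scaling convention behind the fractional-polynomial transform,
  and published-coefficient reproduction of the age terms is therefore
  not a target. `age_scale` is configurable; the default of 1 is the
  convention under which the published age coefficients, taken at face
  value, produce a realistic age gradient (~e⁰·¹ per year around age
  60) and the observed ~10-year case/non-case age gap. Mean-centring
  is applied to the FP *terms*, never to age itself (log of a centred
  age is undefined below the mean).
- **Value-deviation vs slope-deviation.** Only the value-scale
  deviation `b0 + 5 b1` enters the hazard; hazard-ratio units per
  analyte unit make this the natural reading, but a slope-only variant
  would be a one-line change in `trend_deviation`.
- **Platelet units.** Conventional platelet counts are 10⁹/L; the
  package uses that unit label throughout and treats the deviation HR
  as per 10⁹/L.
- **c-statistic flavour.** Harrell's c on the censored outcome is the
  default; for binary (uncensored) coding it equals the trapezoidal
  ROC area computed by the threshold module (tested).

## Problem sizes

The test suite fits cohorts of 800–12,000 patients (inflated event
rate), which exercises every code path in seconds while leaving Monte
Carlo error small relative to the assertion tolerances; the acceptance
script uses 50,000 patients per sex for coefficient recovery and 20,000
for the calibration-slope identity — sizes at which the recovered
hazard ratios' 95% CIs are a few percent wide. These are the package's
reference experiment sizes; larger cohorts only tighten the intervals.

## Known limitations

- The two-stage estimator is not the full joint likelihood; with very
  informative trajectories (large deviation effects or dense
  measurement schedules) the separation between longitudinal fit and
  hazard fit can bias variance components slightly (informative
  sampling of the longitudinal process by survival is ignored).
- The mixed model assumes Gaussian residuals and random effects;
  heavy-tailed lab error is clipped only by the plausible-range filter.
- IPCW Brier assumes censoring independent of covariates.
- The Newton Cox fitter targets cohorts with thousands of events; it
  materialises an n×p×p cumulative array and is not tuned for p beyond
  a dozen covariates.
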