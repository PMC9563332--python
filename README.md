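# fbctrend

Dynamic two-year colorectal-cancer risk prediction from full blood count
(FBC) trends, for biostatisticians and methods researchers working on
joint longitudinal / time-to-event risk models in primary care.

Colorectal tumours often perturb routine blood results years before
diagnosis — haemoglobin and mean corpuscular volume drift down, platelet
counts drift up — while each individual result stays inside its normal
reference range. A clinician looking at the latest FBC sees nothing; a
model looking at the *trend* can. `fbctrend` implements a sex-stratified
multivariate joint model that turns a patient's five-year FBC history
into an absolute two-year risk of colorectal-cancer diagnosis:

1. **Mixed-effects sub-models** (one per analyte): for analyte value
   `y_ij` of patient `i` at window time `t` (years, baseline FBC at
   `t = 5`),

   `y_ij = β₀ + f_age(age_i) + f_time(t_ij) [+ δ·age_i·t_ij] + b0_i + b1_i·t_ij + ε_ij`

   with linear splines `f_age` (knots 60/70/80 for HB, 55 for MCV, 60
   for platelets), `f_time` (knot at year 3), an age×time interaction
   for haemoglobin only, and patient-level random intercept/slope
   `(b0, b1) ~ N(0, G)` with unstructured `G`. Fitted by REML.

2. **Trend deviations**: the BLUP `b̂0 + 5·b̂1` — the patient's
   departure, in analyte units, from the average population trajectory
   at the baseline FBC.

3. **Cox sub-model**: proportional hazards on the fractional-polynomial
   age pair `(a², a²·log a)` and the three trend deviations, Breslow tie
   handling, with the Breslow baseline survivor probability `S₀(2)` at
   mean-centred covariates. Absolute risk is
   `risk = 1 − S₀(2)^exp(lp)`.

The package also provides the full study mechanics around the model:
cohort preparation (plausible-range filtering, the 21-month exclusion
window before diagnosis/censoring, baseline anchoring, eligibility,
outcome definition), a validation-metric suite (IPCW Brier score,
Harrell's c, Royston–Sauerbrei D and pseudo-R²_D, calibration slope,
vigintile Kaplan–Meier calibration tables, subgroup reports), percentile
risk-threshold diagnostics with ROC curves, and a synthetic EHR cohort
generator in which the joint model itself is the generative truth — so
the whole pipeline is testable without access to restricted primary-care
data.

## Worked example

```python
from fbctrend import (default_config, simulate_cohort, prepare_cohort,
                      fit_joint_pipeline, performance_report)

cfg = default_config("male", 20000, seed=1, event_rate_multiplier=10)
cohort = simulate_cohort(cfg)                     # patients + measurements + hidden truth
prep = prepare_cohort(cohort.patients, cohort.measurements)
bundle = fit_joint_pipeline(prep)
print(bundle.cox.hazard_ratios().round(4).to_string(index=False))
```

prints

```
        term    coef     hr  hr_low  hr_high
        age2  0.0142 1.0143  1.0115   1.0171
age2_log_age -0.0029 0.9972  0.9966   0.9977
      dev_hb -0.2128 0.8083  0.7497   0.8714
     dev_mcv -0.0150 0.9851  0.9647   1.0059
     dev_plt  0.0016 1.0016  1.0001   1.0030
```

The generating truth for this cohort had hazard ratios 0.868 per g/dL
of haemoglobin deviation, 0.996 per fL of MCV deviation and 1.001 per
10⁹/L of platelet deviation: a patient trending *below* the population
haemoglobin curve, or *above* the platelet curve, is at elevated risk,
and the two-stage fit recovers this (each true value inside the printed
95% CI). Evaluating the fitted model on its own development cohort:

```python
preds = bundle.predict(prep)
rep = performance_report(preds["risk_2y"].to_numpy(),
                         preds["linear_predictor"].to_numpy(),
                         prep.patients["followup_years"].to_numpy(),
                         prep.patients["event"].to_numpy(int))
```

gives `c = 0.766 (0.745–0.786), D = 1.48, R²_D = 0.34, Brier = 0.0369,
slope = 1.00` — the calibration slope is exactly 1 on development data
(a score-equation identity), and discrimination here comes almost
entirely from age plus the haemoglobin trend. (The Brier score is large
relative to a real screening cohort because this example inflates the
event rate tenfold to stabilise a 20,000-patient fit.)

The same workflow is available from the shell:

```bash
fbctrend simulate --sex male --n 20000 --seed 1 --event-rate-multiplier 10 --out raw/
fbctrend prepare  --patients raw/patients.csv --measurements raw/measurements.csv --out prep/
fbctrend fit      --prepared prep/ --out model.json
fbctrend validate --model model.json --prepared prep/ --subgroups age_band --out val/
fbctrend thresholds --model model.json --prepared prep/ --out thr/
```

## Layout

- `fbctrend.synthetic_cohort` — generator (joint model as truth)
- `fbctrend.cohort_prep` — eligibility, exclusion window, outcomes
- `fbctrend.longitudinal_model` — splines, REML mixed fits, BLUPs
- `fbctrend.risk_model` — Cox sub-model, Breslow baseline, pipeline
- `fbctrend.validation_metrics` — Brier / c / D / R²_D / calibration
- `fbctrend.threshold_analysis` — percentile thresholds, ROC
- `fbctrend.io`, `fbctrend.cli` — files, config, command line

See `docs/methods.md` for the modelling details and design choices.
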