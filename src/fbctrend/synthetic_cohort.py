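"""Synthetic EHR cohort generator with the joint model as generative truth.

The generator emulates the statistical structure the analysis assumes —
nothing more.  Per patient it draws an age at baseline (truncated normal
matching the non-case age moments: males 60.7 (SD 13.0) years on 40-104,
females 61.9 (14.6) on 40-108), a random intercept/slope per analyte from
the configured 2x2 covariances, an irregular FBC panel schedule over the
five-year window (a baseline panel at window time 5 plus Poisson-many
historic panels uniform on [0, 5)), and noisy analyte values from the
mixed-model mean.  The Cox sub-model then *generates* the event times:
with trend deviations d_k = b0 + 5 b1 and the configured log-hazard
coefficients, the time from baseline is

    T = guarantee + Exp(h0 * multiplier * exp(lp - mean lp)),

i.e. a constant (exponential) baseline hazard shifted by the follow-up
guarantee the study design enforces (no diagnosis/censoring within two
years minus three months of baseline).  Proportional hazards are
invariant to that time shift, so the configured hazard ratios are the
estimands the downstream pipeline should recover.  Diagnoses within the
outcome window are cases; everyone else is censored at the earliest of a
random practice-exit and the two-year administrative horizon.

The default outcome window equals the two-year horizon.  Recording
diagnoses *beyond* the censoring cap (the +3-month registry tolerance)
would make the risk sets past the cap consist of future cases only —
censoring informative about the event time — which is immaterial at a
0.3% event rate but ruins parameter recovery at the inflated rates used
for desk-scale fits.  The generator therefore ascertains events within
the horizon; the wider 27-month coding rule lives in
:mod:`fbctrend.cohort_prep`, where it belongs.

Default baseline hazards (0.0084/year male, 0.0078/year female) were
calibrated once so that, with the default coefficient truth, about 0.4%
of males and 0.3% of females are diagnosed within two years at
``event_rate_multiplier = 1``.  Under that truth simulated cases come out
roughly ten years older than non-cases, mirroring the target population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .longitudinal_model import ANALYTES, T_BASELINE, LongitudinalParams
from .risk_model import CoxParams, DAYS_PER_YEAR, fp_age_terms

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "default_config",
    "default_longitudinal_truth",
    "default_cox_truth",
    "sample_event_time",
    "simulate_cohort",
]


def default_longitudinal_truth(sex: str) -> dict[str, LongitudinalParams]:
    """Realistic population-trajectory defaults per analyte.

    These are configuration, chosen to give plausible UK-primary-care
    blood levels and between-patient spread; they are not estimates from
    any restricted dataset.
    """
    male = sex == "male"
    hb = LongitudinalParams(
        analyte="HB",
        intercept=15.4 if male else 14.4,
        age_coefs=[-0.010, -0.020, -0.020, -0.010] if male else [-0.008, -0.010, -0.020, -0.010],
        time_coefs=[-0.020, -0.030] if male else [-0.015, -0.020],
        age_time_interaction=-0.0003 if male else -0.0002,
        re_cov=np.array([[0.9025, -0.0247], [-0.0247, 0.0169]]),
        resid_var=0.3025,  # SD 0.55 g/dL
        age_knots=(60.0, 70.0, 80.0),
    )
    mcv = LongitudinalParams(
        analyte="MCV",
        intercept=86.0 if male else 86.5,
        age_coefs=[0.060, -0.010],
        time_coefs=[0.050, 0.050],
        age_time_interaction=None,
        re_cov=np.array([[10.24, 0.096], [0.096, 0.09]]),
        resid_var=2.89,  # SD 1.7 fL
        age_knots=(55.0,),
    )
    plt = LongitudinalParams(
        analyte="PLT",
        intercept=280.0 if male else 305.0,
        age_coefs=[-0.55, 0.25] if male else [-0.50, 0.20],
        time_coefs=[-1.0, 0.5],
        age_time_interaction=None,
        re_cov=(
            np.array([[2304.0, -26.4], [-26.4, 30.25]])
            if male
            else np.array([[2704.0, -31.2], [-31.2, 36.0]])
        ),
        resid_var=676.0 if male else 784.0,  # SD 26 / 28
        age_knots=(60.0,),
    )
    return {"HB": hb, "MCV": mcv, "PLT": plt}


def default_cox_truth(sex: str) -> CoxParams:
    """Default log-hazard truth for the Cox sub-model, by sex.

    Hazard ratios: age^2 1.015 (male) / 1.014 (female); age^2 log(age)
    0.997 / 0.99717; haemoglobin deviation 0.868 / 0.863 per g/dL; MCV
    0.996 / 0.986 per fL; platelets 1.001 / 1.002 per 10^9/L.  The female
    age^2 log(age) value carries a fourth digit because at three digits
    the two female age terms cancel to a flat age effect; 0.99717 keeps a
    realistic ~10-year case/non-case age gap and rounds to the same three
    digits.  Covariate means and the baseline survivor probability are
    placeholders replaced with cohort-specific values at simulation time.
    """
    if sex == "male":
        hrs = (1.015, 0.997, 0.868, 0.996, 1.001)
    else:
        hrs = (1.014, 0.99717, 0.863, 0.986, 1.002)
    g1, g2, ahb, amcv, aplt = (float(np.log(h)) for h in hrs)
    return CoxParams(
        gamma_age2=g1,
        gamma_age2log=g2,
        alpha_hb=ahb,
        alpha_mcv=amcv,
        alpha_plt=aplt,
        covariate_means=np.zeros(5),
        s0_2y=1.0,
        age_scale=1.0,
    )


@dataclass
class SimulationConfig:
    """All knobs of the generator; a fixed seed reproduces bit-identically."""

    n_patients: int
    sex: str = "male"
    age_mean: float = 60.7
    age_sd: float = 13.0
    age_min: float = 40.0
    age_max: float = 104.0
    visits_mean: float = 3.2  # mean FBC panels per patient over 5y (incl. baseline)
    missing_rate: float = 0.03  # per-analyte missingness per panel
    longitudinal_truth: Mapping[str, LongitudinalParams] = field(default_factory=dict)
    cox_truth: CoxParams | None = None
    baseline_hazard: float = 0.0084  # events per person-year at the mean predictor
    event_rate_multiplier: float = 1.0
    followup_guarantee_years: float = 1.75  # 21 months: the design's exclusion guarantee
    outcome_window_years: float = 2.0  # events ascertained within the horizon
    horizon_years: float = 2.0
    random_exit_rate: float = 0.1  # per-year hazard of leaving the practice
    baseline_date_start: str = "2008-01-01"
    baseline_date_end: str = "2011-10-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.visits_mean < 1:
            raise ValueError("visits_mean must be >= 1 (baseline panel always exists)")
        if self.baseline_hazard <= 0 or self.event_rate_multiplier <= 0:
            raise ValueError("hazard rate and multiplier must be positive")
        for analyte, p in self.longitudinal_truth.items():
            if p.resid_var < 0:
                raise ValueError(f"negative residual variance for {analyte}")


def default_config(sex: str, n_patients: int, seed: int = 0, **overrides) -> SimulationConfig:
    """Sex-specific defaults: age moments, coefficient truth, hazards."""
    base = dict(
        n_patients=n_patients,
        sex=sex,
        longitudinal_truth=default_longitudinal_truth(sex),
        cox_truth=default_cox_truth(sex),
        seed=seed,
    )
    if sex == "female":
        base.update(age_mean=61.9, age_sd=14.6, age_max=108.0, baseline_hazard=0.0078)
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class SyntheticCohort:
    """Observable tables plus hidden truth for recovery tests."""

    patients: pd.DataFrame
    measurements: pd.DataFrame
    truth: pd.DataFrame
    true_cox: CoxParams
    config: SimulationConfig

    def to_csv(self, outdir, with_truth: bool = True) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.patients.to_csv(os.path.join(outdir, "patients.csv"), index=False)
        self.measurements.to_csv(os.path.join(outdir, "measurements.csv"), index=False)
        if with_truth:
            self.truth.to_csv(os.path.join(outdir, "truth.csv"), index=False)


def sample_event_time(linear_predictor: float, baseline_rate: float, uniform_draw) -> np.ndarray:
    """Inverse-transform sample from a constant-hazard Cox model.

    ``T = -log(u) / (rate * exp(lp))``: monotone decreasing in the linear
    predictor for a fixed draw, and T -> 0+ as u -> 1-.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    u = np.asarray(uniform_draw, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("uniform draws must lie strictly inside (0, 1)")
    return -np.log(u) / (baseline_rate * np.exp(np.asarray(linear_predictor, dtype=float)))


def _re_factor(cov: np.ndarray, analyte: str) -> np.ndarray:
    """Factor L with L L' = cov; rejects non-PSD naming the analyte."""
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ValueError(f"random-effects covariance for {analyte} is not symmetric")
    w, V = np.linalg.eigh(cov)
    if np.any(w < -1e-10 * max(1.0, float(np.max(np.abs(w))))):
        raise ValueError(
            f"random-effects covariance for {analyte} is not positive semi-definite"
        )
    return V * np.sqrt(np.clip(w, 0.0, None))


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate one cohort (see module docstring for the mechanism)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    truth_long = config.longitudinal_truth or default_longitudinal_truth(config.sex)
    cox = config.cox_truth or default_cox_truth(config.sex)

    pid = np.array([f"{config.sex[0].upper()}{i:07d}" for i in range(n)])

    a, b = (
        (config.age_min - config.age_mean) / config.age_sd,
        (config.age_max - config.age_mean) / config.age_sd,
    )
    age = truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng)

    start = pd.Timestamp(config.baseline_date_start)
    end = pd.Timestamp(config.baseline_date_end)
    baseline_date = start + pd.to_timedelta(
        rng.integers(0, (end - start).days + 1, size=n), unit="D"
    )

    # visit schedule: baseline panel at t=5 plus Poisson historic panels
    n_hist = rng.poisson(config.visits_mean - 1.0, size=n)
    n_vis = n_hist + 1
    g = np.repeat(np.arange(n), n_vis)
    t = rng.uniform(0.0, T_BASELINE, size=g.size)
    is_baseline = np.concatenate([[True] + [False] * k for k in n_hist])
    t[is_baseline] = T_BASELINE

    # random effects and analyte values
    res: dict[str, np.ndarray] = {}
    frames = []
    for analyte in ANALYTES:
        p = truth_long[analyte]
        L = _re_factor(p.re_cov, analyte)
        bmat = rng.standard_normal((n, 2)) @ L.T
        res[analyte] = bmat
        mu = p.population_mean(age[g], t)
        eps = rng.standard_normal(g.size) * np.sqrt(p.resid_var)
        y = mu + bmat[g, 0] + bmat[g, 1] * t + eps
        keep = rng.random(g.size) >= config.missing_rate
        frames.append(
            pd.DataFrame(
                {"patient_id": pid[g[keep]], "analyte": analyte,
                 "value": y[keep], "_g": g[keep], "_t": t[keep]}
            )
        )
    meas = pd.concat(frames, ignore_index=True)
    meas["date"] = baseline_date[meas["_g"]] - pd.to_timedelta(
        np.round((T_BASELINE - meas["_t"]) * DAYS_PER_YEAR).astype(int), unit="D"
    )

    # trend-deviation covariates at the baseline time, and the linear predictor
    dev = {a_: res[a_][:, 0] + T_BASELINE * res[a_][:, 1] for a_ in ANALYTES}
    a2, a2l = fp_age_terms(age, cox.age_scale)
    Xcov = np.column_stack([a2, a2l, dev["HB"], dev["MCV"], dev["PLT"]])
    lp_raw = Xcov @ cox.coefs
    lp_c = lp_raw - lp_raw.mean()

    rate = config.baseline_hazard * config.event_rate_multiplier
    u = rng.uniform(np.nextafter(0.0, 1.0), 1.0, size=n)
    guarantee = config.followup_guarantee_years
    t_event = guarantee + sample_event_time(lp_c, rate, u)
    if config.random_exit_rate > 0:
        t_exit = guarantee + rng.exponential(1.0 / config.random_exit_rate, size=n)
    else:
        t_exit = np.full(n, np.inf)

    event = (t_event <= config.outcome_window_years) & (t_event <= t_exit)
    t_cens = np.minimum(t_exit, config.horizon_years)
    t_end = np.where(event, t_event, t_cens)
    exit_reason = np.where(
        event, "diagnosis", np.where(t_exit < config.horizon_years, "left_practice", "admin")
    )
    end_date = baseline_date + pd.to_timedelta(
        np.round(t_end * DAYS_PER_YEAR).astype(int), unit="D"
    )
    diagnosis_date = pd.Series(pd.NaT, index=range(n), dtype="datetime64[ns]")
    diagnosis_date[event] = end_date[event]

    entry_offset = rng.uniform(0.5, 3.0, size=n)  # years before the window start
    entry_date = baseline_date - pd.to_timedelta(
        np.round((T_BASELINE + entry_offset) * DAYS_PER_YEAR).astype(int), unit="D"
    )
    birth_date = baseline_date - pd.to_timedelta(
        np.round(age * DAYS_PER_YEAR).astype(int), unit="D"
    )

    patients = pd.DataFrame(
        {
            "patient_id": pid,
            "sex": config.sex,
            "birth_date": birth_date,
            "birth_year": birth_date.year,
            "age_at_baseline": age,
            "entry_date": entry_date,
            "exit_date": end_date,
            "exit_reason": exit_reason,
            "diagnosis_date": diagnosis_date.to_numpy(),
        }
    )

    # hidden truth, kept apart from the observable tables
    h_eff = rate * np.exp(lp_c)
    true_s0 = float(np.exp(-rate * max(config.horizon_years - guarantee, 0.0)))
    truth = pd.DataFrame(
        {
            "patient_id": pid,
            "age": age,
            **{f"b0_{a_.lower()}": res[a_][:, 0] for a_ in ANALYTES},
            **{f"b1_{a_.lower()}": res[a_][:, 1] for a_ in ANALYTES},
            **{f"dev_{a_.lower()}": dev[a_] for a_ in ANALYTES},
            "lp_centred": lp_c,
            "risk_2y_true": 1.0 - true_s0 ** np.exp(lp_c),
            "t_event": t_event,
            "t_exit": t_exit,
            "event": event.astype(int),
        }
    )
    true_cox = replace(
        cox,
        covariate_means=Xcov.mean(axis=0),
        s0_2y=true_s0 if true_s0 < 1.0 else 1.0 - 1e-12,
    )

    measurements = meas[["patient_id", "analyte", "value", "date"]].sort_values(
        ["patient_id", "date", "analyte"], kind="stable"
    ).reset_index(drop=True)
    return SyntheticCohort(
        patients=patients,
        measurements=measurements,
        truth=truth,
        true_cox=true_cox,
        config=config,
    )
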