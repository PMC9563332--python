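"""Cox sub-model and the two-stage joint fit.

The survival half of the joint model is a Cox proportional-hazards model
over five covariates: a repeated-power fractional-polynomial pair in age
at baseline FBC, ``(a^2, a^2 log a)`` with ``a = age / age_scale``, and
the three analyte trend deviations extracted from the mixed sub-models
(per g/dL of haemoglobin, per fL of MCV, per 10^9/L of platelets).  Ties
are handled by Breslow's method, and the absolute two-year risk is

    risk = 1 - S0(2) ** exp(lp),

with ``lp`` the mean-centred linear predictor and ``S0(2)`` the Breslow
baseline survivor probability at two years (baseline = covariates at
their cohort means).

Estimation is two-stage: the three mixed models are fitted by REML, BLUP
trend deviations are extracted, and the Cox model is fitted to them.
This targets the same estimands as a simultaneous joint maximisation and
keeps the fit tractable at EHR scale; because the BLUP is a conditional
mean, the deviation measurement error is Berkson-type (independent of
the covariate actually used), which leaves the hazard ratios essentially
unbiased at the rare event rates this model operates at.
"""

from __future__ import annotations

import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .longitudinal_model import (
    ANALYTES,
    T_BASELINE,
    LongitudinalParams,
    RandomEffects,
    estimate_random_effects,
    estimate_random_effects_batch,
    fit_mixed_model,
    trend_deviation,
)

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

COX_TERMS = ("age2", "age2_log_age", "dev_hb", "dev_mcv", "dev_plt")


def fp_age_terms(age, age_scale: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Repeated-power-2 fractional-polynomial pair ``(a^2, a^2 log a)``.

    ``a = age / age_scale``.  At ``age == age_scale`` this is (1, 0).
    """
    age = np.asarray(age, dtype=float)
    if np.any(age <= 0):
        raise ValueError("age must be positive for the FP transform")
    a = age / age_scale
    a2 = a * a
    return a2, a2 * np.log(a)


@dataclass
class CoxParams:
    """Cox sub-model parameters plus the Breslow two-year baseline.

    Log-hazard coefficients: ``gamma_age2`` and ``gamma_age2log`` per unit
    of the FP age terms; ``alpha_hb/mcv/plt`` per analyte-unit trend
    deviation.  ``covariate_means`` centres the five covariates (FP terms
    first) so that ``s0_2y`` is the survivor probability of a patient at
    the cohort means.
    """

    gamma_age2: float
    gamma_age2log: float
    alpha_hb: float
    alpha_mcv: float
    alpha_plt: float
    covariate_means: np.ndarray
    s0_2y: float
    age_scale: float = 1.0
    se: dict | None = None
    n_events: int = 0
    n: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        self.covariate_means = np.asarray(self.covariate_means, dtype=float)
        if self.covariate_means.shape != (5,):
            raise ValueError("covariate_means must have 5 entries")
        if not (0.0 < self.s0_2y <= 1.0):
            raise ValueError("s0_2y must lie in (0, 1]")

    @property
    def coefs(self) -> np.ndarray:
        return np.array(
            [self.gamma_age2, self.gamma_age2log,
             self.alpha_hb, self.alpha_mcv, self.alpha_plt]
        )

    def covariates(self, age, dev_hb, dev_mcv, dev_plt) -> np.ndarray:
        a2, a2l = fp_age_terms(age, self.age_scale)
        cols = np.broadcast_arrays(
            a2, a2l,
            np.asarray(dev_hb, float),
            np.asarray(dev_mcv, float),
            np.asarray(dev_plt, float),
        )
        return np.stack(cols, axis=-1)

    def linear_predictor(self, age, dev_hb, dev_mcv, dev_plt) -> np.ndarray:
        """Mean-centred prognostic index."""
        X = self.covariates(age, dev_hb, dev_mcv, dev_plt)
        return (X - self.covariate_means) @ self.coefs

    def hazard_ratios(self) -> pd.DataFrame:
        """HRs with 95% CIs, ``exp(coef +/- 1.96 SE)``."""
        coefs = self.coefs
        se = np.array([self.se.get(t, np.nan) for t in COX_TERMS]) if self.se else np.full(5, np.nan)
        return pd.DataFrame(
            {
                "term": COX_TERMS,
                "coef": coefs,
                "hr": np.exp(coefs),
                "hr_low": np.exp(coefs - 1.96 * se),
                "hr_high": np.exp(coefs + 1.96 * se),
            }
        )

    def to_dict(self) -> dict:
        return {
            "gamma_age2": self.gamma_age2,
            "gamma_age2log": self.gamma_age2log,
            "alpha_hb": self.alpha_hb,
            "alpha_mcv": self.alpha_mcv,
            "alpha_plt": self.alpha_plt,
            "covariate_means": self.covariate_means.tolist(),
            "s0_2y": self.s0_2y,
            "age_scale": self.age_scale,
            "se": self.se,
            "n_events": self.n_events,
            "n": self.n,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CoxParams":
        return cls(
            gamma_age2=float(d["gamma_age2"]),
            gamma_age2log=float(d["gamma_age2log"]),
            alpha_hb=float(d["alpha_hb"]),
            alpha_mcv=float(d["alpha_mcv"]),
            alpha_plt=float(d["alpha_plt"]),
            covariate_means=np.asarray(d["covariate_means"], dtype=float),
            s0_2y=float(d["s0_2y"]),
            age_scale=float(d.get("age_scale", 1.0)),
            se=d.get("se"),
            n_events=int(d.get("n_events", 0)),
            n=int(d.get("n", 0)),
            converged=bool(d.get("converged", True)),
        )


# ---------------------------------------------------------------------------
# Partial likelihood with Breslow ties
# ---------------------------------------------------------------------------


def cox_partial_loglik(time, event, X, beta) -> float:
    """Breslow-ties Cox partial log-likelihood (oracle-checkable)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    X = np.asarray(X, float)
    beta = np.asarray(beta, float)
    order = np.argsort(time, kind="stable")
    ts, es, Xs = time[order], event[order], X[order]
    eta = Xs @ beta
    w = np.exp(eta)
    s0 = np.cumsum(w[::-1])[::-1]  # suffix sums
    first = np.searchsorted(ts, ts, side="left")  # risk set start per row
    idx = np.flatnonzero(es == 1)
    return float(np.sum(eta[idx] - np.log(s0[first[idx]])))


def _cox_newton(time, event, X, max_iter: int = 50, tol: float = 1e-9):
    """Newton-Raphson maximisation of the Breslow partial likelihood.

    Returns (beta, cov, loglik, converged).  Covariates should be centred
    by the caller for numerical stability.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    X = np.asarray(X, float)
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    ts, es, Xs = time[order], event[order], X[order]
    first = np.searchsorted(ts, ts, side="left")
    eidx = np.flatnonzero(es == 1)
    fe = first[eidx]

    def loglik_grad_hess(beta):
        eta = Xs @ beta
        eta = np.clip(eta, -500, 500)
        w = np.exp(eta)
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
        wxx = w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :])
        s2 = np.cumsum(wxx[::-1], axis=0)[::-1]
        m = s1[fe] / s0[fe, None]
        ll = float(np.sum(eta[eidx] - np.log(s0[fe])))
        grad = Xs[eidx].sum(axis=0) - m.sum(axis=0)
        hess = -(s2[fe] / s0[fe, None, None] - m[:, :, None] * m[:, None, :]).sum(axis=0)
        return ll, grad, hess

    beta = np.zeros(p)
    ll, grad, hess = loglik_grad_hess(beta)
    converged = False
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        # step halving
        factor = 1.0
        for _ in range(30):
            cand = beta + factor * step
            ll_new, g_new, h_new = loglik_grad_hess(cand)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, grad, hess = cand, ll_new, g_new, h_new
        if np.max(np.abs(grad)) < tol or np.max(np.abs(factor * step)) < tol:
            converged = True
            break
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(-hess)
    return beta, cov, ll, converged


def breslow_baseline_survival(time, event, lp_centred, horizon: float = 2.0) -> float:
    """Breslow baseline survivor probability at ``horizon``.

    ``S0(t) = exp(-H0(t))`` with ``H0(t) = sum_{event times <= t}
    d_k / sum_{j at risk} exp(lp_j)``; the linear predictor must already be
    centred at the covariate means so the baseline refers to an average
    patient.  With all-zero covariates this reduces to the Nelson-Aalen
    estimator.  Non-increasing in the horizon.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    lp = np.asarray(lp_centred, float)
    if horizon > time.max():
        logger.warning(
            "[risk] horizon %.3g beyond last follow-up %.3g; using last event time",
            horizon, time.max(),
        )
        horizon = time.max()
    order = np.argsort(time, kind="stable")
    ts, es, w = time[order], event[order], np.exp(lp[order])
    s0 = np.cumsum(w[::-1])[::-1]
    first = np.searchsorted(ts, ts, side="left")
    mask = (es == 1) & (ts <= horizon)
    h0 = float(np.sum(1.0 / s0[first[mask]]))
    return float(np.exp(-h0))


def fit_cox(
    followup_years,
    event,
    age,
    dev_hb,
    dev_mcv,
    dev_plt,
    age_scale: float = 1.0,
    horizon: float = 2.0,
) -> CoxParams:
    """Fit the five-covariate Cox sub-model and its Breslow baseline."""
    time = np.asarray(followup_years, float)
    ev = np.asarray(event, int)
    n_events = int(ev.sum())
    if n_events < 2:
        raise ValueError(f"need at least 2 events to fit the Cox sub-model, got {n_events}")
    a2, a2l = fp_age_terms(age, age_scale)
    X = np.column_stack([a2, a2l, dev_hb, dev_mcv, dev_plt])
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariates passed to fit_cox")
    means = X.mean(axis=0)
    Xc = X - means
    # drop constant columns from the iteration (no information; coef 0)
    keep = Xc.std(axis=0) > 0
    beta = np.zeros(5)
    cov = np.zeros((5, 5))
    if keep.any():
        b, c, ll, convd = _cox_newton(time, ev, Xc[:, keep])
        beta[keep] = b
        cov[np.ix_(keep, keep)] = c
    else:
        convd = True
    if not convd:
        logger.warning("[risk] Cox sub-model did not converge")
    se = dict(zip(COX_TERMS, np.sqrt(np.clip(np.diag(cov), 0, None))))
    lp_c = Xc @ beta
    s0 = breslow_baseline_survival(time, ev, lp_c, horizon=horizon)
    return CoxParams(
        gamma_age2=float(beta[0]),
        gamma_age2log=float(beta[1]),
        alpha_hb=float(beta[2]),
        alpha_mcv=float(beta[3]),
        alpha_plt=float(beta[4]),
        covariate_means=means,
        s0_2y=s0,
        age_scale=age_scale,
        se=se,
        n_events=n_events,
        n=len(time),
        converged=bool(convd),
    )


def two_year_risk(params: CoxParams, age, dev_hb, dev_mcv, dev_plt):
    """Absolute two-year risk ``1 - s0_2y ** exp(lp)``.

    Returns ``(lp, risk)`` arrays; risk is strictly increasing in the
    linear predictor and bounded in (0, 1).
    """
    lp = params.linear_predictor(age, dev_hb, dev_mcv, dev_plt)
    risk = 1.0 - params.s0_2y ** np.exp(lp)
    return lp, risk


# ---------------------------------------------------------------------------
# Two-stage pipeline and the serialisable bundle
# ---------------------------------------------------------------------------


@dataclass
class ModelBundle:
    """Full fitted model: three mixed sub-models + Cox sub-model."""

    longitudinal: Mapping[str, LongitudinalParams]
    cox: CoxParams
    meta: dict = field(default_factory=dict)

    def patient_deviations(self, cohort) -> pd.DataFrame:
        """BLUP trend deviations for every patient of a prepared cohort."""
        out = cohort.patients[["patient_id"]].copy()
        for analyte in ANALYTES:
            blups = estimate_random_effects_batch(self.longitudinal[analyte], cohort)
            dev = blups.set_index("patient_id")["deviation"]
            out[f"dev_{analyte.lower()}"] = (
                out["patient_id"].map(dev).fillna(0.0).to_numpy()
            )
        return out

    def predict(self, cohort) -> pd.DataFrame:
        """Per-patient linear predictor and absolute two-year risk."""
        devs = self.patient_deviations(cohort)
        age = cohort.patients["age_at_baseline"].to_numpy(float)
        lp, risk = two_year_risk(
            self.cox, age,
            devs["dev_hb"].to_numpy(), devs["dev_mcv"].to_numpy(),
            devs["dev_plt"].to_numpy(),
        )
        return pd.DataFrame(
            {
                "patient_id": cohort.patients["patient_id"].to_numpy(),
                "linear_predictor": lp,
                "risk_2y": risk,
            }
        )

    def to_dict(self) -> dict:
        return {
            "longitudinal": {a: p.to_dict() for a, p in self.longitudinal.items()},
            "cox": self.cox.to_dict(),
            "meta": self.meta,
        }

    def save(self, path) -> None:
        """Atomic JSON write (temp file + rename)."""
        payload = json.dumps(self.to_dict(), indent=2)
        d = os.path.dirname(os.path.abspath(path)) or "."
        fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
        try:
            with os.fdopen(fd, "w") as fh:
                fh.write(payload)
            os.replace(tmp, path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise

    @classmethod
    def from_dict(cls, d: dict) -> "ModelBundle":
        return cls(
            longitudinal={
                a: LongitudinalParams.from_dict(p) for a, p in d["longitudinal"].items()
            },
            cox=CoxParams.from_dict(d["cox"]),
            meta=d.get("meta", {}),
        )

    @classmethod
    def load(cls, path) -> "ModelBundle":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_joint_pipeline(cohort, age_scale: float = 1.0, horizon: float = 2.0) -> ModelBundle:
    """Two-stage joint fit: mixed models -> BLUP deviations -> Cox + Breslow.

    Sex stratification is by fitting disjoint cohorts; this function fits
    whatever cohort it is given.  Errors from any stage propagate with the
    stage named.
    """
    longitudinal: dict[str, LongitudinalParams] = {}
    for analyte in ANALYTES:
        try:
            longitudinal[analyte] = fit_mixed_model(cohort, analyte)
        except Exception as exc:
            raise RuntimeError(f"mixed-model stage failed for {analyte}: {exc}") from exc
    bundle = ModelBundle(longitudinal=longitudinal, cox=None, meta={})  # type: ignore[arg-type]
    devs = bundle.patient_deviations(cohort)
    pats = cohort.patients
    try:
        cox = fit_cox(
            pats["followup_years"].to_numpy(float),
            pats["event"].to_numpy(int),
            pats["age_at_baseline"].to_numpy(float),
            devs["dev_hb"].to_numpy(),
            devs["dev_mcv"].to_numpy(),
            devs["dev_plt"].to_numpy(),
            age_scale=age_scale,
            horizon=horizon,
        )
    except Exception as exc:
        raise RuntimeError(f"Cox stage failed: {exc}") from exc
    bundle.cox = cox
    sexes = sorted(pats["sex"].unique().tolist()) if "sex" in pats else []
    bundle.meta = {
        "n_patients": int(len(pats)),
        "n_events": int(pats["event"].sum()),
        "sex": sexes,
        "age_scale": age_scale,
        "horizon_years": horizon,
    }
    return bundle


def predict_patient(bundle: ModelBundle, history: pd.DataFrame, age_at_baseline: float) -> dict:
    """Dynamic per-patient prediction from an FBC history.

    ``history`` has columns (analyte, value, date); the newest measurement
    date anchors the five-year window (window time 5), and only
    measurements within the window contribute.  Re-calling after appending
    a new FBC yields the updated (dynamic) risk.  ``age_at_baseline`` is
    the patient's age at the newest FBC.
    """
    if history is None or len(history) == 0:
        raise ValueError("empty FBC history; need at least one measurement")
    hist = history.copy()
    hist["date"] = pd.to_datetime(hist["date"])
    anchor = hist["date"].max()
    hist["window_time"] = (
        T_BASELINE - (anchor - hist["date"]).dt.days / DAYS_PER_YEAR
    )
    hist = hist[hist["window_time"] >= 0]
    if hist.empty:
        raise ValueError("no measurements inside the five-year window")
    devs = {}
    for analyte in ANALYTES:
        sub = hist[hist["analyte"] == analyte]
        re = estimate_random_effects(
            bundle.longitudinal[analyte],
            sub["window_time"].to_numpy(float),
            sub["value"].to_numpy(float),
            age_at_baseline,
        )
        devs[analyte] = trend_deviation(re)
    lp, risk = two_year_risk(
        bundle.cox, age_at_baseline, devs["HB"], devs["MCV"], devs["PLT"]
    )
    return {
        "baseline_date": anchor,
        "age_at_baseline": float(age_at_baseline),
        "deviations": {a: float(devs[a]) for a in ANALYTES},
        "linear_predictor": float(lp),
        "risk_2y": float(risk),
    }
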