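"""Per-analyte linear mixed models for five-year FBC trends.

Each full-blood-count analyte (haemoglobin HB in g/dL, mean corpuscular
volume MCV in fL, platelet count PLT in 10^9/L) gets its own linear
mixed-effects model over the five-year longitudinal window:

    y_ij = beta0 + f_age(age_i) + f_time(t_ij) [+ delta * age_i * t_ij]
           + b0_i + b1_i * t_ij + eps_ij

where ``f_age`` and ``f_time`` are linear splines (knots at ages 60/70/80
for HB, 55 for MCV, 60 for PLT; time knot at year 3), ``age_i`` is age at
the baseline FBC (constant within patient), ``t_ij`` in [0, 5] is time in
the window with the baseline FBC at t = 5, and ``(b0_i, b1_i)`` is a
patient-level random intercept/slope with unstructured 2x2 covariance G.
The age x time interaction is included for haemoglobin only.

Estimation is REML, computed from per-patient cross-products so that
cohorts with tens of thousands of patients fit in seconds.  Per-patient
random effects are extracted as BLUPs (the conditional mean of (b0, b1)
given the patient's residuals) and summarised as the *trend deviation*
``b0 + b1 * t_baseline``: the patient's departure, in analyte units, from
the average population trajectory at the baseline FBC.  These deviations
are the covariates of the Cox sub-model (see :mod:`fbctrend.risk_model`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

ANALYTES = ("HB", "MCV", "PLT")

#: default linear-spline knots, in years of age, per analyte
DEFAULT_AGE_KNOTS: Mapping[str, tuple[float, ...]] = {
    "HB": (60.0, 70.0, 80.0),
    "MCV": (55.0,),
    "PLT": (60.0,),
}

#: default knot (years) for time in the five-year window
DEFAULT_TIME_KNOTS: tuple[float, ...] = (3.0,)

#: baseline FBC sits at the end of the five-year window
T_BASELINE = 5.0


@dataclass(frozen=True)
class SplineSpec:
    """Linear-spline specification: basis ``[x, (x-k1)+, (x-k2)+, ...]``."""

    knots: tuple[float, ...]

    def __post_init__(self) -> None:
        ks = tuple(float(k) for k in self.knots)
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError(f"spline knots must be strictly increasing, got {ks}")
        object.__setattr__(self, "knots", ks)

    @property
    def n_terms(self) -> int:
        return 1 + len(self.knots)


def linear_spline_basis(x, spec: SplineSpec) -> np.ndarray:
    """Evaluate the linear-spline basis at ``x``.

    Returns an array of shape ``(..., 1 + n_knots)`` with columns
    ``x, max(x - k, 0)`` per knot; the implied fit is continuous and
    piecewise linear in ``x``.
    """
    x = np.asarray(x, dtype=float)
    cols = [x] + [np.maximum(x - k, 0.0) for k in spec.knots]
    return np.stack(cols, axis=-1)


@dataclass
class LongitudinalParams:
    """Parameters of one analyte's mixed model.

    ``age_coefs`` / ``time_coefs`` align with :func:`linear_spline_basis`
    applied to the corresponding knot list; ``re_cov`` is the 2x2
    unstructured covariance of (intercept, slope) random effects in
    analyte units (squared); ``resid_var`` the residual variance.
    """

    analyte: str
    intercept: float
    age_coefs: np.ndarray
    time_coefs: np.ndarray
    re_cov: np.ndarray
    resid_var: float
    age_time_interaction: float | None = None
    age_knots: tuple[float, ...] = ()
    time_knots: tuple[float, ...] = DEFAULT_TIME_KNOTS
    n_obs: int = 0
    n_patients: int = 0
    loglik: float = float("nan")
    converged: bool = True
    fixed_cov: np.ndarray | None = None  # covariance of fixed effects

    def __post_init__(self) -> None:
        self.age_coefs = np.asarray(self.age_coefs, dtype=float)
        self.time_coefs = np.asarray(self.time_coefs, dtype=float)
        self.re_cov = np.asarray(self.re_cov, dtype=float)
        if self.re_cov.shape != (2, 2):
            raise ValueError("re_cov must be 2x2")
        if not np.allclose(self.re_cov, self.re_cov.T, atol=1e-10):
            raise ValueError("re_cov must be symmetric")
        if self.resid_var < 0:
            raise ValueError("resid_var must be non-negative")

    @property
    def age_spec(self) -> SplineSpec:
        return SplineSpec(self.age_knots)

    @property
    def time_spec(self) -> SplineSpec:
        return SplineSpec(self.time_knots)

    def population_mean(self, age, t) -> np.ndarray:
        """Average population trajectory at baseline-age ``age``, window time ``t``."""
        age = np.asarray(age, dtype=float)
        t = np.asarray(t, dtype=float)
        mu = (
            self.intercept
            + linear_spline_basis(age, self.age_spec) @ self.age_coefs
            + linear_spline_basis(t, self.time_spec) @ self.time_coefs
        )
        if self.age_time_interaction is not None:
            mu = mu + self.age_time_interaction * age * t
        return mu

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "analyte": self.analyte,
            "intercept": self.intercept,
            "age_coefs": self.age_coefs.tolist(),
            "time_coefs": self.time_coefs.tolist(),
            "age_time_interaction": self.age_time_interaction,
            "re_cov": self.re_cov.tolist(),
            "resid_var": self.resid_var,
            "age_knots": list(self.age_knots),
            "time_knots": list(self.time_knots),
            "n_obs": self.n_obs,
            "n_patients": self.n_patients,
            "loglik": None if np.isnan(self.loglik) else self.loglik,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LongitudinalParams":
        return cls(
            analyte=d["analyte"],
            intercept=float(d["intercept"]),
            age_coefs=np.asarray(d["age_coefs"], dtype=float),
            time_coefs=np.asarray(d["time_coefs"], dtype=float),
            age_time_interaction=d.get("age_time_interaction"),
            re_cov=np.asarray(d["re_cov"], dtype=float),
            resid_var=float(d["resid_var"]),
            age_knots=tuple(d.get("age_knots", ())),
            time_knots=tuple(d.get("time_knots", DEFAULT_TIME_KNOTS)),
            n_obs=int(d.get("n_obs", 0)),
            n_patients=int(d.get("n_patients", 0)),
            loglik=float("nan") if d.get("loglik") is None else float(d["loglik"]),
            converged=bool(d.get("converged", True)),
        )


@dataclass(frozen=True)
class RandomEffects:
    """BLUP of one patient's (intercept, slope) deviation, analyte units."""

    b0: float
    b1: float


def trend_deviation(re: RandomEffects, t_baseline: float = T_BASELINE) -> float:
    """Patient's value-scale departure from the population trend at baseline.

    ``b0 + b1 * t_baseline``; zero when both random effects are zero.
    """
    return re.b0 + re.b1 * t_baseline


# ---------------------------------------------------------------------------
# REML machinery
# ---------------------------------------------------------------------------


def _design_matrix(
    age: np.ndarray,
    t: np.ndarray,
    age_spec: SplineSpec,
    time_spec: SplineSpec,
    interaction: bool,
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(t)]
    names = ["intercept"]
    ab = linear_spline_basis(age, age_spec)
    for j, k in enumerate(["age"] + [f"age_k{k:g}" for k in age_spec.knots]):
        cols.append(ab[:, j])
        names.append(k)
    tb = linear_spline_basis(t, time_spec)
    for j, k in enumerate(["time"] + [f"time_k{k:g}" for k in time_spec.knots]):
        cols.append(tb[:, j])
        names.append(k)
    if interaction:
        cols.append(age * t)
        names.append("age_x_time")
    return np.column_stack(cols), names


class _CrossProducts:
    """Per-patient sufficient statistics for the 2-random-effect REML fit.

    With z_ij = (1, t_ij), everything the restricted likelihood needs is
    expressible through S_i = Z_i'Z_i (2x2), C_i = Z_i'X_i (2xp),
    v_i = Z_i'y_i (2,) and the global X'X, X'y, y'y.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, t: np.ndarray, g: np.ndarray):
        n_groups = int(g.max()) + 1
        n, p = X.shape
        self.n, self.p, self.n_groups = n, p, n_groups
        self.s_n = np.bincount(g, minlength=n_groups).astype(float)
        self.s_t = np.bincount(g, weights=t, minlength=n_groups)
        self.s_tt = np.bincount(g, weights=t * t, minlength=n_groups)
        S = np.empty((n_groups, 2, 2))
        S[:, 0, 0] = self.s_n
        S[:, 0, 1] = S[:, 1, 0] = self.s_t
        S[:, 1, 1] = self.s_tt
        self.S = S
        # C0[g] = sum_j x_j, C1[g] = sum_j t_j x_j  (rows of Z_g' X_g)
        C0 = np.empty((n_groups, p))
        C1 = np.empty((n_groups, p))
        for j in range(p):
            C0[:, j] = np.bincount(g, weights=X[:, j], minlength=n_groups)
            C1[:, j] = np.bincount(g, weights=X[:, j] * t, minlength=n_groups)
        self.C0, self.C1 = C0, C1
        self.v0 = np.bincount(g, weights=y, minlength=n_groups)
        self.v1 = np.bincount(g, weights=y * t, minlength=n_groups)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def gls_pieces(self, D: np.ndarray):
        """A = X'W X, b = X'W y, q = y'W y, logdets, with W = (I + Z D Z')^-1.

        Uses (I + Z D Z')^-1 = I - Z M Z' with M = D (I2 + S D)^-1, so
        everything reduces to elementwise 2x2 algebra over groups plus
        four p x p GEMMs.
        """
        d11, d12, d22 = D[0, 0], D[0, 1], D[1, 1]
        # entries of I2 + S D
        a11 = 1.0 + self.s_n * d11 + self.s_t * d12
        a12 = self.s_n * d12 + self.s_t * d22
        a21 = self.s_t * d11 + self.s_tt * d12
        a22 = 1.0 + self.s_t * d12 + self.s_tt * d22
        det = a11 * a22 - a12 * a21
        if np.any(det <= 0):
            return None
        # M = D (I2 + S D)^-1
        m11 = (d11 * a22 - d12 * a21) / det
        m12 = (-d11 * a12 + d12 * a11) / det
        m21 = (d12 * a22 - d22 * a21) / det
        m22 = (-d12 * a12 + d22 * a11) / det
        C0, C1, v0, v1 = self.C0, self.C1, self.v0, self.v1
        A = self.XtX - (
            C0.T @ (m11[:, None] * C0)
            + C0.T @ (m12[:, None] * C1)
            + C1.T @ (m21[:, None] * C0)
            + C1.T @ (m22[:, None] * C1)
        )
        u0 = m11 * v0 + m12 * v1
        u1 = m21 * v0 + m22 * v1
        b = self.Xty - (C0.T @ u0 + C1.T @ u1)
        q = self.yty - float(v0 @ u0 + v1 @ u1)
        sum_logdet = float(np.sum(np.log(det)))
        return A, b, q, sum_logdet

    def reml_criterion(self, D: np.ndarray) -> float:
        """-2 restricted log-likelihood with beta and sigma^2 profiled out
        (additive constants dropped)."""
        pieces = self.gls_pieces(D)
        if pieces is None:
            return np.inf
        A, b, q, sum_logdet = pieces
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return np.inf
        rss = q - beta @ b
        if not np.isfinite(rss) or rss <= 0:
            return np.inf
        sig2 = rss / (self.n - self.p)
        sign, ldA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        return sum_logdet + ldA + (self.n - self.p) * np.log(sig2)


def _unpack_chol(theta: np.ndarray) -> np.ndarray:
    """theta = (log l11, log l22, l21) -> D = L L' (ratio G / sigma^2)."""
    L = np.array([[np.exp(theta[0]), 0.0], [theta[2], np.exp(theta[1])]])
    return L @ L.T


def _pack_chol(D: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(D)
    return np.array([np.log(L[0, 0]), np.log(L[1, 1]), L[1, 0]])


def _moment_start(cp: _CrossProducts, y, X, t, g) -> np.ndarray:
    """Method-of-moments start for D = G / sigma^2.

    Per-patient OLS estimates of (b0, b1) on the fixed-effect residuals
    have covariance G + sigma^2 (Z'Z)^-1; subtracting the average noise
    term gives a crude G.  Only patients with >= 3 measurements and a
    decent time spread contribute, otherwise the noise correction is
    dominated by near-singular (Z'Z)^-1 terms.  The REML surface can
    hold a local minimum with collapsed slope variance, so starting near
    the right scale matters more than starting precisely.
    """
    fallback = np.array([0.0, -1.6, 0.0])
    try:
        beta = np.linalg.solve(cp.XtX, cp.Xty)
    except np.linalg.LinAlgError:
        return fallback
    r = y - X @ beta
    n_g = cp.n_groups
    v = np.empty((n_g, 2))
    v[:, 0] = np.bincount(g, weights=r, minlength=n_g)
    v[:, 1] = np.bincount(g, weights=r * t, minlength=n_g)
    S = cp.S
    n_i = S[:, 0, 0]
    spread = S[:, 1, 1] - S[:, 0, 1] ** 2 / np.maximum(n_i, 1.0)
    usable = (n_i >= 3) & (spread >= 1.0)
    if usable.sum() < 5:
        usable = (n_i >= 2) & (spread >= 0.25)
    if usable.sum() < 5:
        return fallback
    Su, vu = S[usable], v[usable]
    detu = Su[:, 0, 0] * Su[:, 1, 1] - Su[:, 0, 1] ** 2
    Sinv = np.empty_like(Su)
    Sinv[:, 0, 0] = Su[:, 1, 1]
    Sinv[:, 1, 1] = Su[:, 0, 0]
    Sinv[:, 0, 1] = Sinv[:, 1, 0] = -Su[:, 0, 1]
    Sinv /= detu[:, None, None]
    bhat = np.einsum("gij,gj->gi", Sinv, vu)
    # residual variance from the detrended within-patient scatter
    rss_g = np.bincount(g, weights=r * r, minlength=n_g)[usable] - np.einsum(
        "gi,gi->g", vu, bhat
    )
    df = float(np.sum(S[usable, 0, 0] - 2))
    s2 = float(np.sum(np.clip(rss_g, 0, None)) / max(df, 1.0))
    if not np.isfinite(s2) or s2 <= 0:
        return fallback
    G0 = np.cov(bhat.T) - s2 * Sinv.mean(axis=0)
    w, V = np.linalg.eigh(G0)
    w = np.clip(w, 1e-3 * s2, None)
    D0 = (V * w) @ V.T / s2
    th = _pack_chol(D0)
    return th if np.all(np.isfinite(th)) else fallback


def reml_criterion(y, X, t, groups, D) -> float:
    """Profiled REML criterion (-2 restricted loglik up to a constant) at
    variance-ratio matrix ``D = G / sigma^2``.  Exposed for oracle tests."""
    g, _ = pd.factorize(np.asarray(groups))
    cp = _CrossProducts(np.asarray(y, float), np.asarray(X, float), np.asarray(t, float), g)
    return cp.reml_criterion(np.asarray(D, float))


def fit_mixed_model(
    cohort,
    analyte: str,
    age_spec: SplineSpec | None = None,
    time_spec: SplineSpec | None = None,
    interaction: bool | None = None,
    maxiter: int = 2000,
) -> LongitudinalParams:
    """Fit one analyte's mixed model by REML on a prepared cohort.

    ``cohort`` needs a ``measurements`` frame (patient_id, analyte, value,
    window_time) and a ``patients`` frame (patient_id, age_at_baseline).
    The fit is deterministic: a Nelder-Mead search over the Cholesky factor
    of G / sigma^2 from a fixed start, with beta and sigma^2 profiled out.
    """
    if analyte not in ANALYTES:
        raise ValueError(f"unknown analyte {analyte!r}; expected one of {ANALYTES}")
    if age_spec is None:
        age_spec = SplineSpec(DEFAULT_AGE_KNOTS[analyte])
    if time_spec is None:
        time_spec = SplineSpec(DEFAULT_TIME_KNOTS)
    if interaction is None:
        interaction = analyte == "HB"

    meas = cohort.measurements
    sub = meas[meas["analyte"] == analyte]
    if sub.empty:
        raise ValueError(f"no measurements for analyte {analyte!r}")
    ages = cohort.patients.set_index("patient_id")["age_at_baseline"]
    sub = sub[sub["patient_id"].isin(ages.index)]
    g, uniq = pd.factorize(sub["patient_id"])
    if len(uniq) < 2:
        raise ValueError("need at least 2 patients to fit a mixed model")
    t = sub["window_time"].to_numpy(dtype=float)
    y = sub["value"].to_numpy(dtype=float)
    age = ages.loc[uniq].to_numpy(dtype=float)[g]

    # centring y keeps the criterion away from catastrophic cancellation
    # in y'y - (fit terms); only the intercept shifts, restored below
    ybar = float(y.mean())
    y = y - ybar

    X, names = _design_matrix(age, t, age_spec, time_spec, interaction)
    # full-rank check, naming the collinear columns
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R = np.linalg.qr(X)
        bad = [names[j] for j in range(X.shape[1]) if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise ValueError(f"singular fixed-effect design; collinear columns: {bad}")

    cp = _CrossProducts(y, X, t, g)
    obj = lambda th: cp.reml_criterion(_unpack_chol(th))
    theta0 = _moment_start(cp, y, X, t, g)

    def _nm(th0):
        return minimize(
            obj,
            th0,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": maxiter, "maxfev": maxiter},
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = _nm(theta0)
        if not res.success:
            # fresh simplex from the incumbent finishes the slow NM tail
            res2 = _nm(res.x)
            if res2.fun <= res.fun:
                res = res2
        # the surface can trap a collapsed slope variance; retry from an
        # inflated-slope start when the fit fell far below its start
        if res.x[1] < theta0[1] - np.log(5.0):
            res2 = _nm(theta0 + np.array([0.0, np.log(3.0), 0.0]))
            if res2.fun < res.fun:
                res = res2
    if not res.success:
        logger.warning(
            "[longitudinal] REML for %s did not meet convergence tolerance "
            "(nfev=%d, fun=%.6g)", analyte, res.nfev, res.fun,
        )
    D = _unpack_chol(res.x)
    A, b, q, sum_logdet = cp.gls_pieces(D)
    beta = np.linalg.solve(A, b)
    rss = q - beta @ b
    sig2 = rss / (cp.n - cp.p)
    loglik = -0.5 * (res.fun + (cp.n - cp.p) * (1.0 + np.log(2 * np.pi)))
    fixed_cov = sig2 * np.linalg.inv(A)

    na = age_spec.n_terms
    nt = time_spec.n_terms
    return LongitudinalParams(
        analyte=analyte,
        intercept=float(beta[0]) + ybar,
        age_coefs=beta[1 : 1 + na],
        time_coefs=beta[1 + na : 1 + na + nt],
        age_time_interaction=float(beta[-1]) if interaction else None,
        re_cov=sig2 * D,
        resid_var=float(sig2),
        age_knots=age_spec.knots,
        time_knots=time_spec.knots,
        n_obs=cp.n,
        n_patients=cp.n_groups,
        loglik=float(loglik),
        converged=bool(res.success),
        fixed_cov=fixed_cov,
    )


def fixed_effects_table(params: LongitudinalParams) -> pd.DataFrame:
    """Point estimates with asymptotic 95% CIs for the fixed effects."""
    names = ["intercept"]
    names += ["age"] + [f"age_k{k:g}" for k in params.age_knots]
    names += ["time"] + [f"time_k{k:g}" for k in params.time_knots]
    est = [params.intercept, *params.age_coefs, *params.time_coefs]
    if params.age_time_interaction is not None:
        names.append("age_x_time")
        est.append(params.age_time_interaction)
    est = np.asarray(est)
    if params.fixed_cov is None:
        se = np.full(est.shape, np.nan)
    else:
        se = np.sqrt(np.diag(params.fixed_cov))
    return pd.DataFrame(
        {"term": names, "estimate": est, "se": se,
         "ci_low": est - 1.96 * se, "ci_high": est + 1.96 * se}
    )


# ---------------------------------------------------------------------------
# BLUPs
# ---------------------------------------------------------------------------


def estimate_random_effects(
    params: LongitudinalParams,
    times: Sequence[float],
    values: Sequence[float],
    age: float,
) -> RandomEffects:
    """BLUP of one patient's (b0, b1) given their measurements.

    Conditional mean ``G Z' (Z G Z' + sigma^2 I)^-1 r`` with residuals
    r = y - population mean, computed through the equivalent 2x2 system
    ``G (Z'Z G + sigma^2 I)^-1 Z'r`` (valid for singular G; shrinks to
    (0, 0) as G -> 0 or as within-patient information vanishes).
    A patient with no measurements of the analyte falls back to the
    population mean, i.e. (0, 0), with a logged warning.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size == 0:
        logger.warning(
            "[longitudinal] no %s measurements for BLUP; using population mean",
            params.analyte,
        )
        return RandomEffects(0.0, 0.0)
    r = y - params.population_mean(age, t)
    Z = np.column_stack([np.ones_like(t), t])
    S = Z.T @ Z
    v = Z.T @ r
    G = params.re_cov
    b = G @ np.linalg.solve(S @ G + params.resid_var * np.eye(2), v)
    return RandomEffects(float(b[0]), float(b[1]))


def estimate_random_effects_batch(params: LongitudinalParams, cohort) -> pd.DataFrame:
    """Vectorised BLUPs for every patient in a prepared cohort.

    Returns a frame indexed like ``cohort.patients`` with columns b0, b1 and
    the value-scale trend deviation at t = 5.  Patients without any
    measurement of the analyte get zeros (population-mean fallback).
    """
    meas = cohort.measurements
    pats = cohort.patients
    ages = pats.set_index("patient_id")["age_at_baseline"]
    sub = meas[(meas["analyte"] == params.analyte) & meas["patient_id"].isin(ages.index)]

    pid_codes, uniq = pd.factorize(pats["patient_id"])
    code_of = pd.Series(np.arange(len(uniq)), index=uniq)
    g = code_of.loc[sub["patient_id"]].to_numpy()
    t = sub["window_time"].to_numpy(dtype=float)
    y = sub["value"].to_numpy(dtype=float)
    age = ages.loc[sub["patient_id"]].to_numpy(dtype=float)
    r = y - params.population_mean(age, t)

    n_g = len(uniq)
    S = np.zeros((n_g, 2, 2))
    S[:, 0, 0] = np.bincount(g, minlength=n_g)
    st = np.bincount(g, weights=t, minlength=n_g)
    S[:, 0, 1] = S[:, 1, 0] = st
    S[:, 1, 1] = np.bincount(g, weights=t * t, minlength=n_g)
    v = np.empty((n_g, 2))
    v[:, 0] = np.bincount(g, weights=r, minlength=n_g)
    v[:, 1] = np.bincount(g, weights=r * t, minlength=n_g)

    n_missing = int((S[:, 0, 0] == 0).sum())
    if n_missing:
        logger.warning(
            "[longitudinal] %d patients have no %s measurements; population-mean fallback",
            n_missing, params.analyte,
        )

    G = params.re_cov
    A = S @ G + params.resid_var * np.eye(2)[None, :, :]
    det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
    det = np.where(det == 0, 1.0, det)  # patients with no data: v = 0 anyway
    Ainv = np.empty_like(A)
    Ainv[:, 0, 0] = A[:, 1, 1]
    Ainv[:, 1, 1] = A[:, 0, 0]
    Ainv[:, 0, 1] = -A[:, 0, 1]
    Ainv[:, 1, 0] = -A[:, 1, 0]
    Ainv /= det[:, None, None]
    b = np.einsum("ij,gjk,gk->gi", G, Ainv, v)

    out = pd.DataFrame(
        {
            "patient_id": uniq,
            "b0": b[:, 0],
            "b1": b[:, 1],
        }
    )
    out["deviation"] = out["b0"] + T_BASELINE * out["b1"]
    return out
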