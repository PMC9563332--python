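"""Prognostic-model validation metrics.

Implements the full performance suite for a fitted risk model evaluated
on a (possibly censored) cohort:

* IPCW Brier score at the two-year horizon (inverse probability of
  censoring weights from a Kaplan-Meier fit to the censoring
  distribution; reduces to the plain mean squared error when nobody is
  censored before the horizon);
* Harrell's c-statistic over usable pairs, with a Hanley-McNeil-type
  asymptotic confidence interval;
* Royston-Sauerbrei D-statistic: the Cox coefficient of the prognostic
  index's expected normal order statistics (Blom scores) divided by
  kappa = sqrt(8/pi), with its closed-form pseudo R^2
  ``R2_D = (D^2/kappa^2) / (pi^2/6 + D^2/kappa^2)``;
* calibration slope (Cox coefficient of the prognostic index; 1 means
  neither over- nor under-fitting) and 20-bin (vigintile) calibration
  tables with Kaplan-Meier observed risks;
* the same report per subgroup (10-year age bands 40-90, number of FBCs,
  six-month FBC-span bands).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.utils import concordance_index
from scipy.stats import norm, rankdata

from .risk_model import _cox_newton

logger = logging.getLogger(__name__)

KAPPA2 = 8.0 / np.pi  # kappa^2 in the D-statistic construction
PI2_6 = np.pi**2 / 6.0


@dataclass
class PerformanceReport:
    """Full metric set for one cohort or subgroup."""

    label: str
    n: int
    n_events: int
    brier: float | None = None
    c_statistic: float | None = None
    c_ci: tuple[float, float] | None = None
    d_statistic: float | None = None
    d_ci: tuple[float, float] | None = None
    r2_d: float | None = None
    calibration_slope: float | None = None
    calibration_bins: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "label": self.label,
            "n": self.n,
            "n_events": self.n_events,
            "brier": self.brier,
            "c_statistic": self.c_statistic,
            "c_ci": list(self.c_ci) if self.c_ci else None,
            "d_statistic": self.d_statistic,
            "d_ci": list(self.d_ci) if self.d_ci else None,
            "r2_d": self.r2_d,
            "calibration_slope": self.calibration_slope,
            "warnings": self.warnings,
        }
        if self.calibration_bins is not None:
            d["calibration_bins"] = self.calibration_bins.to_dict(orient="records")
        return d


def concordance(risks, followup_years, event) -> tuple[float, tuple[float, float]]:
    """Harrell's c over usable pairs, with an asymptotic 95% CI.

    A pair is usable when the ordering of survival is identifiable
    (shorter time is an event); tied predictions get half credit.  The
    CI uses the Hanley-McNeil variance approximation with the event /
    non-event counts, a Noether-type normal interval.
    """
    risks = np.asarray(risks, float)
    t = np.asarray(followup_years, float)
    e = np.asarray(event, int)
    if e.sum() == 0 or (e == 0).sum() + (e.sum() >= 2) == 0:
        raise ValueError("no comparable pairs: need at least one event")
    # higher risk should mean shorter survival
    c = concordance_index(t, -risks, e)
    n1 = int(e.sum())
    n2 = int((e == 0).sum())
    if n2 == 0:
        n2 = max(n1 - 1, 1)
    q1 = c / (2.0 - c)
    q2 = 2.0 * c * c / (1.0 + c)
    var = (c * (1 - c) + (n1 - 1) * (q1 - c * c) + (n2 - 1) * (q2 - c * c)) / (n1 * n2)
    half = 1.96 * np.sqrt(max(var, 0.0))
    return float(c), (float(c - half), float(c + half))


def brier_two_year(risks, followup_years, event, horizon: float = 2.0) -> float:
    """IPCW Brier score at the horizon.

    Weights: events before the horizon 1/G(T-), survivors past the
    horizon 1/G(horizon-), censored-before-horizon patients 0, where G is
    the Kaplan-Meier survivor function of the censoring distribution.
    """
    risks = np.asarray(risks, float)
    t = np.asarray(followup_years, float)
    e = np.asarray(event, int)
    cens_km = KaplanMeierFitter()
    cens_km.fit(t, 1 - e)
    eps = 1e-9

    died = (t <= horizon) & (e == 1)
    alive = t >= horizon  # includes admin censoring exactly at the horizon
    w = np.zeros(len(t))
    g_at = np.asarray(cens_km.predict(np.maximum(t[died] - eps, 0.0)), float)
    g_h = float(cens_km.predict(horizon - eps))
    if np.any(g_at <= 0) or (alive.any() and g_h <= 0):
        raise ValueError("censoring survivor estimate is 0 at a needed time")
    w[died] = 1.0 / g_at
    w[alive] = 1.0 / g_h
    ind = died.astype(float)
    return float(np.mean(w * (ind - risks) ** 2))


def _cox_univariate(x, t, e) -> tuple[float, float]:
    """Coefficient and SE from a single-covariate Cox fit."""
    x = np.asarray(x, float)
    xc = x - x.mean()
    if xc.std() == 0:
        raise ValueError("covariate is constant")
    beta, cov, _, _ = _cox_newton(np.asarray(t, float), np.asarray(e, int), xc[:, None])
    return float(beta[0]), float(np.sqrt(max(cov[0, 0], 0.0)))


def royston_d(prognostic_index, followup_years, event) -> tuple[float, tuple[float, float]]:
    """Royston-Sauerbrei D: prognostic separation on a hazard scale.

    Ranks the PI, maps ranks to expected standard-normal order statistics
    via Blom's approximation ``Phi^-1((r - 3/8)/(n + 1/4))``, divides by
    kappa = sqrt(8/pi), and Cox-regresses survival on the score; D is the
    fitted coefficient.  Invariant to strictly increasing transforms of
    the PI by construction.  All-tied PI gives D = 0 by convention.
    """
    pi = np.asarray(prognostic_index, float)
    n = len(pi)
    if np.ptp(pi) == 0:
        logger.warning("[metrics] all prognostic indices tied; D = 0 by convention")
        return 0.0, (0.0, 0.0)
    r = rankdata(pi)
    z = norm.ppf((r - 3.0 / 8.0) / (n + 0.25)) / np.sqrt(KAPPA2)
    beta, se = _cox_univariate(z, followup_years, event)
    return beta, (beta - 1.96 * se, beta + 1.96 * se)


def r2_from_d(d: float) -> float:
    """Closed-form pseudo R^2 of the D-statistic.

    ``R2_D = (D^2/kappa^2) / (pi^2/6 + D^2/kappa^2)`` with kappa^2 = 8/pi;
    monotone increasing in |D| and bounded in [0, 1).
    """
    s = d * d / KAPPA2
    return s / (PI2_6 + s)


def calibration_slope(prognostic_index, followup_years, event) -> float:
    """Cox coefficient of the PI on the evaluation data (1 = perfect)."""
    e = np.asarray(event, int)
    if e.sum() == 0:
        raise ValueError("no events; calibration slope undefined")
    beta, _ = _cox_univariate(prognostic_index, followup_years, e)
    return beta


def calibration_bins(
    risks, followup_years, event, g: int = 20, horizon: float = 2.0
) -> pd.DataFrame:
    """Vigintile calibration table.

    Splits the cohort into ``g`` equal-sized groups (sizes differ by at
    most 1) of predicted risk; per group reports the mean predicted risk
    and the Kaplan-Meier observed risk ``1 - KM(horizon)``.
    """
    risks = np.asarray(risks, float)
    t = np.asarray(followup_years, float)
    e = np.asarray(event, int)
    n = len(risks)
    if n < g:
        raise ValueError(f"need at least {g} patients for {g} bins, got {n}")
    order = np.argsort(risks, kind="stable")
    rows = []
    for k, idx in enumerate(np.array_split(order, g)):
        km = KaplanMeierFitter()
        km.fit(t[idx], e[idx])
        upper = min(horizon, t[idx].max())
        observed = 1.0 - float(km.predict(upper))
        rows.append(
            {
                "bin": k + 1,
                "n": len(idx),
                "n_events": int(e[idx].sum()),
                "mean_predicted": float(risks[idx].mean()),
                "observed_km": observed,
            }
        )
    return pd.DataFrame(rows)


def performance_report(
    risks,
    prognostic_index,
    followup_years,
    event,
    label: str = "overall",
    g: int = 20,
    horizon: float = 2.0,
    min_events: int = 10,
) -> PerformanceReport:
    """Assemble the full metric set; metric failures become warnings."""
    t = np.asarray(followup_years, float)
    e = np.asarray(event, int)
    rep = PerformanceReport(label=label, n=len(t), n_events=int(e.sum()))
    if rep.n_events < min_events:
        rep.warnings.append(
            f"only {rep.n_events} events; estimates unstable / wide CIs"
        )
    steps = {
        "brier": lambda: setattr(rep, "brier", brier_two_year(risks, t, e, horizon)),
        "c": lambda: (lambda c, ci: (setattr(rep, "c_statistic", c), setattr(rep, "c_ci", ci)))(
            *concordance(risks, t, e)
        ),
        "d": lambda: (lambda d, ci: (
            setattr(rep, "d_statistic", d),
            setattr(rep, "d_ci", ci),
            setattr(rep, "r2_d", r2_from_d(d)),
        ))(*royston_d(prognostic_index, t, e)),
        "slope": lambda: setattr(
            rep, "calibration_slope", calibration_slope(prognostic_index, t, e)
        ),
        "bins": lambda: setattr(rep, "calibration_bins", calibration_bins(risks, t, e, g, horizon)),
    }
    for name, step in steps.items():
        try:
            step()
        except Exception as exc:  # keep the rest of the report usable
            rep.warnings.append(f"{name}: {exc}")
    return rep


# ---------------------------------------------------------------------------
# Subgroups
# ---------------------------------------------------------------------------

SUBGROUP_DIMENSIONS = ("age_band", "n_fbc", "fbc_span")


def subgroup_labels(patients: pd.DataFrame, dimension: str) -> pd.Series:
    """Subgroup membership per patient.

    ``age_band``: 10-year bands from 40 to 90, then 90+; ``n_fbc``:
    number of FBC dates (1, 2, ..., 14, 15+); ``fbc_span``: six-month
    bands of the window time span between first and last FBC.
    """
    if dimension == "age_band":
        edges = [40, 50, 60, 70, 80, 90, np.inf]
        labels = ["40-49", "50-59", "60-69", "70-79", "80-89", "90+"]
        return pd.cut(patients["age_at_baseline"], edges, right=False, labels=labels).astype(str)
    if dimension == "n_fbc":
        n = patients["n_fbc"].clip(upper=15)
        return n.map(lambda k: "15+" if k >= 15 else str(int(k)))
    if dimension == "fbc_span":
        edges = np.arange(0.0, 5.5, 0.5)
        span = patients["fbc_span_years"].clip(0, 5 - 1e-9)
        lab = np.floor(span / 0.5).astype(int)
        return lab.map(lambda k: f"{k * 0.5:.1f}-{(k + 1) * 0.5:.1f}y")
    raise ValueError(f"unknown subgroup dimension {dimension!r}; expected {SUBGROUP_DIMENSIONS}")


def subgroup_performance(
    predictions: pd.DataFrame,
    patients: pd.DataFrame,
    dimension: str,
    g: int = 20,
    horizon: float = 2.0,
    min_events: int = 10,
) -> list[PerformanceReport]:
    """One :class:`PerformanceReport` per non-empty subgroup.

    ``predictions`` carries patient_id, linear_predictor, risk_2y;
    ``patients`` the prepared patient table (followup_years, event, and
    the subgroup helper columns).
    """
    merged = patients.merge(predictions, on="patient_id", validate="one_to_one")
    labels = subgroup_labels(merged, dimension)
    reports = []
    for lab in sorted(labels.unique()):
        sub = merged[labels == lab]
        rep = performance_report(
            sub["risk_2y"].to_numpy(),
            sub["linear_predictor"].to_numpy(),
            sub["followup_years"].to_numpy(),
            sub["event"].to_numpy(),
            label=f"{dimension}={lab}",
            g=min(g, max(len(sub) // 2, 1)),
            horizon=horizon,
            min_events=min_events,
        )
        reports.append(rep)
    return reports
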