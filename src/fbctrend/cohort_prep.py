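"""Study-design mechanics: eligibility, exclusion window, baseline, outcome.

The preparation pipeline turns raw long-format tables (one row per analyte
measurement, one row per patient) into the analysis cohort:

1. drop measurements outside biologically plausible ranges;
2. drop measurements inside the exclusion window (default 21 months
   before the diagnosis/censor date), so predictions use only data from
   at least ~2 years before diagnosis;
3. anchor each patient's five-year longitudinal clock at the most recent
   retained FBC (the *baseline*, window time 5) and keep measurements
   within the window (time in [0, 5]);
4. apply eligibility (age >= 40 at baseline, >= 1 measurement of each of
   HB/MCV/PLT, >= 1 year of registration before baseline);
5. define the outcome: diagnosis within the outcome window after
   baseline (default 27 months) is an event; otherwise censoring at the
   earliest exit, capped at two years of follow-up.

The asymmetric 21/27-month pairing realises "two years (+/- three
months)": all FBCs less than 21 months before diagnosis/censor are
removed, so every retained patient has at least 21 months of follow-up
after baseline, and cases are those diagnosed up to 27 months after it.
Dates are handled in days and converted to years by /365.25.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .longitudinal_model import ANALYTES, T_BASELINE

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

#: configurable plausible ranges per analyte (lo, hi) in analyte units
DEFAULT_PLAUSIBLE_RANGES = {
    "HB": (3.0, 25.0),     # g/dL
    "MCV": (50.0, 150.0),  # fL
    "PLT": (10.0, 1500.0), # 10^9/L
}

DEFAULT_EXCLUSION_MONTHS = 21.0
DEFAULT_OUTCOME_MONTHS = 27.0
DEFAULT_HORIZON_YEARS = 2.0


def _months_to_days(months: float) -> float:
    return months * DAYS_PER_YEAR / 12.0


@dataclass
class PreparedCohort:
    """Analysis-ready cohort.

    ``patients``: one row per retained patient with age_at_baseline,
    baseline_date, event (1 diagnosed / 0 censored), followup_years and
    subgroup helpers (n_fbc, fbc_span_years).  ``measurements``: one row
    per retained measurement with window_time in [0, 5] (baseline at 5).
    ``flow``: per-step exclusion counts.
    """

    patients: pd.DataFrame
    measurements: pd.DataFrame
    flow: dict = field(default_factory=dict)


def apply_plausible_ranges(
    measurements: pd.DataFrame, ranges: dict | None = None
) -> tuple[pd.DataFrame, dict]:
    """Drop values outside the configured [lo, hi] per analyte.

    Every analyte present in the data must have a configured range.
    Returns the filtered table and per-analyte drop counts.
    """
    ranges = dict(DEFAULT_PLAUSIBLE_RANGES if ranges is None else ranges)
    observed = set(measurements["analyte"].unique())
    missing = observed - set(ranges)
    if missing:
        raise ValueError(f"no plausible range configured for analyte(s): {sorted(missing)}")
    lo = measurements["analyte"].map({a: r[0] for a, r in ranges.items()})
    hi = measurements["analyte"].map({a: r[1] for a, r in ranges.items()})
    ok = (measurements["value"] >= lo) & (measurements["value"] <= hi)
    dropped = measurements.loc[~ok, "analyte"].value_counts().to_dict()
    for a, n in dropped.items():
        logger.info("[prep] dropped %d %s values outside plausible range", n, a)
    return measurements.loc[ok].copy(), {a: int(dropped.get(a, 0)) for a in sorted(observed)}


def apply_exclusion_window(
    measurements: pd.DataFrame,
    end_dates: pd.Series,
    window_months: float = DEFAULT_EXCLUSION_MONTHS,
) -> pd.DataFrame:
    """Drop measurements dated inside the exclusion window.

    ``end_dates`` maps patient_id -> diagnosis-or-censor date; a
    measurement is removed when ``date > end_date - window``.  Patients
    left with no measurements disappear from the cohort downstream.
    """
    if end_dates.isna().any():
        bad = end_dates[end_dates.isna()].index.tolist()[:5]
        raise ValueError(f"missing diagnosis/censor date for patients {bad}")
    end = measurements["patient_id"].map(end_dates)
    if end.isna().any():
        bad = measurements.loc[end.isna(), "patient_id"].unique()[:5].tolist()
        raise ValueError(f"no end date for patients with measurements: {bad}")
    gap_days = (end - measurements["date"]).dt.days
    keep = gap_days >= _months_to_days(window_months)
    return measurements.loc[keep].copy()


def define_outcome(
    baseline_date,
    diagnosis_date,
    exit_date,
    outcome_months: float = DEFAULT_OUTCOME_MONTHS,
    horizon_years: float = DEFAULT_HORIZON_YEARS,
) -> tuple[int, float]:
    """Event indicator and follow-up (years) for one patient.

    Diagnosis within ``outcome_months`` after baseline is an event;
    a later diagnosis, or none, censors the patient at the earliest of
    the exit date and ``horizon_years`` after baseline.
    """
    baseline_date = pd.Timestamp(baseline_date)
    if pd.notna(diagnosis_date):
        diagnosis_date = pd.Timestamp(diagnosis_date)
        if diagnosis_date < baseline_date:
            raise ValueError(
                "diagnosis before baseline violates the exclusion-window contract"
            )
        d_years = (diagnosis_date - baseline_date).days / DAYS_PER_YEAR
        if d_years * 12.0 <= outcome_months + 1e-9:
            return 1, d_years
    if pd.isna(exit_date):
        raise ValueError("censored patient without an exit date")
    fu = (pd.Timestamp(exit_date) - baseline_date).days / DAYS_PER_YEAR
    return 0, float(min(fu, horizon_years))


def filter_eligible(
    patients: pd.DataFrame,
    measurements: pd.DataFrame,
    min_age: float = 40.0,
    min_registration_years: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Eligibility on the (post-exclusion) tables, with flow counts.

    ``patients`` must carry ``age_at_baseline``, ``baseline_date`` and
    ``entry_date``.  Retains patients aged >= ``min_age`` at baseline,
    with at least one retained measurement of each analyte, registered at
    least ``min_registration_years`` before baseline.  Idempotent.
    """
    flow: dict[str, int] = {}
    pats = patients
    has = measurements.groupby("patient_id")["analyte"].agg(set)
    complete = has[has.apply(lambda s: set(ANALYTES) <= s)].index
    keep = pats["patient_id"].isin(complete)
    flow["excluded_missing_analyte"] = int((~keep).sum())
    pats = pats.loc[keep]

    keep = pats["age_at_baseline"] >= min_age
    flow[f"excluded_age_under_{min_age:g}"] = int((~keep).sum())
    pats = pats.loc[keep]

    reg_days = (pats["baseline_date"] - pats["entry_date"]).dt.days
    keep = reg_days >= min_registration_years * DAYS_PER_YEAR
    flow["excluded_registration_under_1y"] = int((~keep).sum())
    pats = pats.loc[keep]
    return pats.copy(), flow


def prepare_cohort(
    patients: pd.DataFrame,
    measurements: pd.DataFrame,
    plausible_ranges: dict | None = None,
    exclusion_months: float = DEFAULT_EXCLUSION_MONTHS,
    outcome_months: float = DEFAULT_OUTCOME_MONTHS,
    horizon_years: float = DEFAULT_HORIZON_YEARS,
    window_years: float = T_BASELINE,
    min_age: float = 40.0,
    min_registration_years: float = 1.0,
) -> PreparedCohort:
    """Run the full preparation pipeline (see module docstring)."""
    pats = patients.copy()
    meas = measurements.copy()
    for col in ("entry_date", "exit_date", "diagnosis_date"):
        if col in pats:
            pats[col] = pd.to_datetime(pats[col])
    if "birth_date" in pats:
        pats["birth_date"] = pd.to_datetime(pats["birth_date"])
    meas["date"] = pd.to_datetime(meas["date"])

    flow: dict[str, int] = {"patients_in": int(len(pats)), "measurements_in": int(len(meas))}

    meas, dropped = apply_plausible_ranges(meas, plausible_ranges)
    flow["measurements_outside_plausible_range"] = dropped

    indexed = pats.set_index("patient_id")
    if "diagnosis_date" in indexed:
        end_dates = indexed["diagnosis_date"].fillna(indexed["exit_date"])
    else:
        end_dates = indexed["exit_date"]
    meas = meas[meas["patient_id"].isin(end_dates.index)]
    n_before = len(meas)
    meas = apply_exclusion_window(meas, end_dates, exclusion_months)
    flow["measurements_in_exclusion_window"] = int(n_before - len(meas))

    # baseline = most recent retained FBC; five-year clock ends there
    baseline = meas.groupby("patient_id")["date"].max().rename("baseline_date")
    n_no_meas = int((~pats["patient_id"].isin(baseline.index)).sum())
    flow["excluded_no_remaining_fbc"] = n_no_meas
    pats = pats[pats["patient_id"].isin(baseline.index)].copy()
    pats["baseline_date"] = pats["patient_id"].map(baseline)

    meas["window_time"] = window_years - (
        meas["patient_id"].map(baseline) - meas["date"]
    ).dt.days / DAYS_PER_YEAR
    n_before = len(meas)
    meas = meas[meas["window_time"] >= 0].copy()
    flow["measurements_before_window"] = int(n_before - len(meas))

    # same-day duplicates of one analyte: average (deterministic tie-break)
    meas = (
        meas.groupby(["patient_id", "analyte", "date"], as_index=False)
        .agg(value=("value", "mean"), window_time=("window_time", "first"))
    )

    if "birth_date" in pats:
        pats["age_at_baseline"] = (
            pats["baseline_date"] - pats["birth_date"]
        ).dt.days / DAYS_PER_YEAR
    elif "age_at_baseline" not in pats:
        raise ValueError("patients table needs birth_date or age_at_baseline")

    pats, elig_flow = filter_eligible(pats, meas, min_age, min_registration_years)
    flow.update(elig_flow)
    meas = meas[meas["patient_id"].isin(pats["patient_id"])].copy()

    # outcome and censoring
    idx = pats.set_index("patient_id")
    events = np.zeros(len(pats), dtype=int)
    fu = np.zeros(len(pats), dtype=float)
    diag = pats["diagnosis_date"] if "diagnosis_date" in pats else pd.Series(pd.NaT, index=pats.index)
    for i, (bd, dd, xd) in enumerate(
        zip(pats["baseline_date"], diag, pats["exit_date"])
    ):
        events[i], fu[i] = define_outcome(bd, dd, xd, outcome_months, horizon_years)
    pats["event"] = events
    pats["followup_years"] = fu

    # subgroup helpers: number of FBC dates and their span inside the window
    by_pat = meas.groupby("patient_id")
    n_fbc = by_pat["date"].nunique()
    span = by_pat["window_time"].max() - by_pat["window_time"].min()
    pats["n_fbc"] = pats["patient_id"].map(n_fbc).astype(int)
    pats["fbc_span_years"] = pats["patient_id"].map(span)

    flow["patients_out"] = int(len(pats))
    flow["events"] = int(pats["event"].sum())
    keep_cols = [
        c
        for c in (
            "patient_id", "sex", "age_at_baseline", "baseline_date",
            "entry_date", "exit_date", "diagnosis_date",
            "event", "followup_years", "n_fbc", "fbc_span_years",
        )
        if c in pats.columns
    ]
    return PreparedCohort(
        patients=pats[keep_cols].reset_index(drop=True),
        measurements=meas.reset_index(drop=True),
        flow=flow,
    )
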