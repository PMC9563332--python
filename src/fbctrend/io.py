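"""Readers/writers and run configuration.

CSV dialect throughout: UTF-8, comma separator, dot decimal, ISO-8601
dates.  Schema problems are reported with the offending column or row.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from .cohort_prep import (
    DEFAULT_EXCLUSION_MONTHS,
    DEFAULT_HORIZON_YEARS,
    DEFAULT_OUTCOME_MONTHS,
    DEFAULT_PLAUSIBLE_RANGES,
    PreparedCohort,
)

PATIENT_COLUMNS = ("patient_id", "sex", "entry_date", "exit_date")
MEASUREMENT_COLUMNS = ("patient_id", "analyte", "value", "date")


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing required column(s) {missing}")


def _parse_dates(df: pd.DataFrame, cols, what: str) -> pd.DataFrame:
    for c in cols:
        if c not in df.columns:
            continue
        parsed = pd.to_datetime(df[c], errors="coerce", format="ISO8601")
        bad = parsed.isna() & df[c].notna() & (df[c].astype(str).str.len() > 0)
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"{what}: unparseable date in column {c!r} at row {row}: {df[c][row]!r}"
            )
        df[c] = parsed
    return df


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, PATIENT_COLUMNS, f"patients table {path}")
    return _parse_dates(
        df, ("birth_date", "entry_date", "exit_date", "diagnosis_date"), f"patients table {path}"
    )


def read_measurements(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, MEASUREMENT_COLUMNS, f"measurements table {path}")
    if not pd.api.types.is_numeric_dtype(df["value"]):
        bad = pd.to_numeric(df["value"], errors="coerce").isna() & df["value"].notna()
        row = int(bad.idxmax()) if bad.any() else -1
        raise ValueError(
            f"measurements table {path}: non-numeric value at row {row}: {df['value'].iloc[row]!r}"
        )
    return _parse_dates(df, ("date",), f"measurements table {path}")


def write_prepared(cohort: PreparedCohort, outdir) -> None:
    """`prepared_cohort.csv` (one row per retained measurement, joined with
    the patient-level outcome columns) plus `flow.json`."""
    os.makedirs(outdir, exist_ok=True)
    merged = cohort.measurements.merge(cohort.patients, on="patient_id", how="left")
    merged.to_csv(os.path.join(outdir, "prepared_cohort.csv"), index=False)
    with open(os.path.join(outdir, "flow.json"), "w") as fh:
        json.dump(cohort.flow, fh, indent=2)


def read_prepared(outdir) -> PreparedCohort:
    path = os.path.join(outdir, "prepared_cohort.csv")
    df = pd.read_csv(path)
    _require_columns(
        df,
        ("patient_id", "analyte", "value", "date", "window_time",
         "age_at_baseline", "event", "followup_years"),
        f"prepared cohort {path}",
    )
    df = _parse_dates(df, ("date", "baseline_date", "entry_date", "exit_date", "diagnosis_date"),
                      f"prepared cohort {path}")
    meas_cols = ["patient_id", "analyte", "value", "date", "window_time"]
    pat_cols = [c for c in df.columns if c not in ("analyte", "value", "date", "window_time")]
    patients = df[pat_cols].drop_duplicates("patient_id").reset_index(drop=True)
    flow_path = os.path.join(outdir, "flow.json")
    flow = {}
    if os.path.exists(flow_path):
        with open(flow_path) as fh:
            flow = json.load(fh)
    return PreparedCohort(patients=patients, measurements=df[meas_cols].copy(), flow=flow)


@dataclass
class RunConfig:
    """End-to-end run settings; defaults reproduce the standard design.

    Age spline knots 60/70/80 (HB), 55 (MCV), 60 (PLT); time knot at year
    3 of the five-year window; 21-month exclusion window; 27-month
    outcome window with a two-year follow-up cap; risk percentiles 75-99.
    """

    sex: str = "male"
    seed: int = 0
    exclusion_months: float = DEFAULT_EXCLUSION_MONTHS
    outcome_months: float = DEFAULT_OUTCOME_MONTHS
    horizon_years: float = DEFAULT_HORIZON_YEARS
    window_years: float = 5.0
    age_scale: float = 1.0
    plausible_ranges: dict = field(
        default_factory=lambda: {a: list(r) for a, r in DEFAULT_PLAUSIBLE_RANGES.items()}
    )
    age_knots: dict = field(
        default_factory=lambda: {"HB": [60.0, 70.0, 80.0], "MCV": [55.0], "PLT": [60.0]}
    )
    time_knot: float = 3.0
    percentiles: list = field(default_factory=lambda: [75, 80, 85, 90, 95, 99])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s) in {path}: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
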