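"""EHR table schemas, validation, and CSV round-trip I/O.

The pipeline consumes six long-format CSV tables, mirroring the way
laboratory and pharmacy systems export data:

``patients``       one row per patient (id, sex, birth date)
``labs``           one row per analyte measurement (TC, HDL, TG,
                   LDL_direct, eGFR); a lipid panel is assembled later by
                   grouping on (patient_id, date)
``diagnoses``      dated diagnosis / intervention / billing events mapped to
                   a closed category set
``prescriptions``  ATC-coded prescription registrations with daily dose for
                   statins
``bp``             dated blood-pressure readings (optional table)
``smoking``        dated current-smoking observations (optional table)

All dates are ISO-8601 calendar dates (day precision).  ``write_tables``
emits deterministic column and row order so that write -> read -> write is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "RowValidationError",
    "CohortConfig",
    "TABLE_COLUMNS",
    "OPTIONAL_TABLES",
    "ANALYTES",
    "DIAGNOSIS_CATEGORIES",
    "CVD_CATEGORIES",
    "read_tables",
    "write_tables",
]


class SchemaError(ValueError):
    """A table is structurally invalid (missing column, unknown table...)."""


class RowValidationError(ValueError):
    """A row violates an invariant; carries the 1-based file line number."""

    def __init__(self, table: str, line: int, message: str):
        self.table = table
        self.line = line
        super().__init__(f"{table}.csv line {line}: {message}")


ANALYTES = ("TC", "HDL", "TG", "LDL_direct", "eGFR")
DIAGNOSIS_CATEGORIES = ("CHD", "STROKE", "PAD", "AAA", "DIABETES", "CKD", "DIALYSIS")
#: categories that establish cardiovascular disease
CVD_CATEGORIES = ("CHD", "STROKE", "PAD", "AAA")

TABLE_COLUMNS: dict[str, list[str]] = {
    "patients": ["patient_id", "sex", "birth_date"],
    "labs": ["patient_id", "date", "analyte", "value"],
    "diagnoses": ["patient_id", "date", "code", "category"],
    "prescriptions": [
        "patient_id",
        "registration_date",
        "atc_code",
        "drug_name",
        "daily_dose_mg",
    ],
    "bp": ["patient_id", "date", "systolic", "diastolic"],
    "smoking": ["patient_id", "date", "smoking_current"],
}
OPTIONAL_TABLES = ("bp", "smoking")

_DATE_COLUMNS = {
    "patients": ["birth_date"],
    "labs": ["date"],
    "diagnoses": ["date"],
    "prescriptions": ["registration_date"],
    "bp": ["date"],
    "smoking": ["date"],
}


@dataclass
class CohortConfig:
    """All analysis thresholds, windows and knobs in one place.

    Units: lipid values mmol/L, eGFR mL/min/1.73m2, windows in days unless
    the field name says otherwise.  Every default is overridable from YAML.
    """

    #: guideline LDL-c target; on target means ldl < ldl_target
    ldl_target: float = 2.5
    #: Friedewald-derived LDL-c below this is unreliable before remeasure_date
    low_ldl_cutoff: float = 0.8
    #: triglycerides above this invalidate the Friedewald derivation
    high_tg_cutoff: float = 8.0
    #: date the laboratory began remeasuring low LDL-c values
    remeasure_date: dt.date = dt.date(2017, 1, 24)
    #: CVD events up to this many days AFTER a measurement still qualify
    #: (captures pre-operative screening)
    cvd_window_days: int = 7
    #: eGFR lookup window around a measurement (applied as +-2 calendar days)
    egfr_window_hours: int = 48
    #: follow-up classification: short = [short_min, short_max] days,
    #: long = (short_max, long_max] days, else unrelated
    short_min_days: int = 61
    short_max_days: int = 183
    long_max_days: int = 548
    #: sequences truncated at this nearest-rank percentile of length
    truncation_percentile: float = 75.0
    n_clusters: int = 4
    indel_cost: float = 1.0
    substitution_method: str = "constant"  # or "trate"
    substitution_constant: float = 2.0
    egfr_ckd_threshold: float = 60.0
    #: blood-pressure lookup window around a measurement
    bp_window_days: int = 7
    #: estimate the transition matrix on truncated sequences instead of all
    #: related pairs
    transitions_on_truncated: bool = False
    #: cap on sequences entering the O(n^2) optimal-matching stage; a seeded
    #: random subsample is taken above this
    max_cluster_sequences: int = 1000

    def __post_init__(self) -> None:
        if isinstance(self.remeasure_date, str):
            self.remeasure_date = dt.date.fromisoformat(self.remeasure_date)
        self.validate()

    def validate(self) -> None:
        if not (0 < self.short_min_days <= self.short_max_days < self.long_max_days):
            raise ValueError(
                "follow-up windows must satisfy 0 < short_min <= short_max < long_max"
            )
        if self.ldl_target <= 0:
            raise ValueError("ldl_target must be positive")
        if not (0 < self.truncation_percentile <= 100):
            raise ValueError("truncation_percentile must be in (0, 100]")
        if self.substitution_method not in ("constant", "trate"):
            raise ValueError("substitution_method must be 'constant' or 'trate'")
        if self.indel_cost <= 0:
            raise ValueError("indel_cost must be positive")

    @property
    def egfr_window_days(self) -> int:
        """eGFR window in whole calendar days (hours rounded up)."""
        return -(-self.egfr_window_hours // 24)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["remeasure_date"] = self.remeasure_date.isoformat()
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------


def _first_bad_line(mask: pd.Series) -> int:
    # data rows start at file line 2 (line 1 is the header)
    return int(mask.idxmax()) + 2


def _parse_dates(df: pd.DataFrame, table: str, cols: list[str]) -> pd.DataFrame:
    for col in cols:
        parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            raise RowValidationError(
                table, _first_bad_line(bad), f"unparseable ISO date in '{col}'"
            )
        if parsed.isna().any():
            raise RowValidationError(
                table, _first_bad_line(parsed.isna()), f"missing date in '{col}'"
            )
        df[col] = parsed
    return df


def _require_columns(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in TABLE_COLUMNS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}.csv: missing required column '{missing[0]}'")


def _validate_patients(df: pd.DataFrame) -> pd.DataFrame:
    bad = ~df["sex"].isin(["female", "male"])
    if bad.any():
        raise RowValidationError("patients", _first_bad_line(bad), "sex must be female/male")
    if df["patient_id"].duplicated().any():
        raise RowValidationError(
            "patients", _first_bad_line(df["patient_id"].duplicated()), "duplicate patient_id"
        )
    return df


def _validate_labs(df: pd.DataFrame) -> pd.DataFrame:
    bad = ~df["analyte"].isin(ANALYTES)
    if bad.any():
        raise SchemaError(
            f"labs.csv line {_first_bad_line(bad)}: unknown analyte "
            f"{df.loc[bad.idxmax(), 'analyte']!r}"
        )
    value = pd.to_numeric(df["value"], errors="coerce")
    bad = value.isna() | (value < 0)
    if bad.any():
        raise RowValidationError("labs", _first_bad_line(bad), "value must be >= 0")
    df["value"] = value.astype(float)
    return df


def _validate_diagnoses(df: pd.DataFrame) -> pd.DataFrame:
    bad = ~df["category"].isin(DIAGNOSIS_CATEGORIES)
    if bad.any():
        raise RowValidationError(
            "diagnoses", _first_bad_line(bad), "category outside the closed set"
        )
    bad = df["code"].isna() | (df["code"].astype(str).str.len() == 0)
    if bad.any():
        raise RowValidationError("diagnoses", _first_bad_line(bad), "empty code")
    return df


def _validate_prescriptions(df: pd.DataFrame) -> pd.DataFrame:
    bad = df["atc_code"].isna() | (df["atc_code"].astype(str).str.len() == 0)
    if bad.any():
        raise RowValidationError("prescriptions", _first_bad_line(bad), "empty atc_code")
    dose = pd.to_numeric(df["daily_dose_mg"], errors="coerce")
    is_statin = df["atc_code"].astype(str).str.startswith("C10AA")
    bad = is_statin & (dose.isna() | (dose <= 0))
    if bad.any():
        raise RowValidationError(
            "prescriptions",
            _first_bad_line(bad),
            "statin rows (ATC C10AA*) require a positive daily_dose_mg",
        )
    bad = dose.notna() & (dose <= 0)
    if bad.any():
        raise RowValidationError(
            "prescriptions", _first_bad_line(bad), "daily_dose_mg must be positive"
        )
    df["daily_dose_mg"] = dose
    return df


def _validate_bp(df: pd.DataFrame) -> pd.DataFrame:
    sys_ = pd.to_numeric(df["systolic"], errors="coerce")
    dia = pd.to_numeric(df["diastolic"], errors="coerce")
    bad = sys_.isna() | dia.isna() | ~(sys_ > dia) | ~(dia > 0)
    if bad.any():
        raise RowValidationError("bp", _first_bad_line(bad), "need systolic > diastolic > 0")
    df["systolic"] = sys_.astype(float)
    df["diastolic"] = dia.astype(float)
    return df


def _validate_smoking(df: pd.DataFrame) -> pd.DataFrame:
    mapped = df["smoking_current"].map(
        {True: True, False: False, "True": True, "False": False}
    )
    if mapped.isna().any():
        raise RowValidationError(
            "smoking", _first_bad_line(mapped.isna()), "smoking_current must be True/False"
        )
    df["smoking_current"] = mapped.astype(bool)
    return df


_VALIDATORS = {
    "patients": _validate_patients,
    "labs": _validate_labs,
    "diagnoses": _validate_diagnoses,
    "prescriptions": _validate_prescriptions,
    "bp": _validate_bp,
    "smoking": _validate_smoking,
}


def validate_tables(tables: Mapping[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Validate in-memory tables against the schemas; returns cleaned copies."""
    out: dict[str, pd.DataFrame] = {}
    for name, df in tables.items():
        if name not in TABLE_COLUMNS:
            raise SchemaError(f"unknown table {name!r}")
        df = df.copy().reset_index(drop=True)
        _require_columns(df, name)
        df = df[TABLE_COLUMNS[name]]
        if len(df):
            df = _parse_dates(df, name, _DATE_COLUMNS[name])
            df = _VALIDATORS[name](df)
        else:
            for col in _DATE_COLUMNS[name]:
                df[col] = pd.to_datetime(df[col])
        out[name] = df
    return out


def read_tables(paths: Mapping[str, str | Path]) -> dict[str, pd.DataFrame]:
    """Read and validate the pipeline input tables.

    Parameters
    ----------
    paths
        Mapping from table name (``patients``, ``labs``, ``diagnoses``,
        ``prescriptions`` and optionally ``bp``, ``smoking``) to a CSV path.
    """
    required = [t for t in TABLE_COLUMNS if t not in OPTIONAL_TABLES]
    missing = [t for t in required if t not in paths]
    if missing:
        raise SchemaError(f"missing required tables: {missing}")
    tables = {}
    for name, path in paths.items():
        if name not in TABLE_COLUMNS:
            raise SchemaError(f"unknown table {name!r}")
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        # round_trip float parsing keeps write -> read -> write byte-stable
        tables[name] = pd.read_csv(path, dtype={"patient_id": str}, float_precision="round_trip")
    return validate_tables(tables)


_SORT_KEYS = {name: cols for name, cols in TABLE_COLUMNS.items()}


def write_tables(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> dict[str, Path]:
    """Write tables as CSV with deterministic column and row order.

    Rows are sorted by every column in schema order (patient_id first, then
    date); dates serialize as ISO-8601.  Re-reading reproduces the input and
    a second write is byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        if name not in TABLE_COLUMNS:
            raise SchemaError(f"unknown table {name!r}")
        df = df[TABLE_COLUMNS[name]].copy()
        df = df.sort_values(_SORT_KEYS[name], kind="mergesort").reset_index(drop=True)
        for col in _DATE_COLUMNS[name]:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path
    return written


def table_paths(in_dir: str | Path) -> dict[str, Path]:
    """Locate the standard table files under a directory (optional tables
    included only when present)."""
    in_dir = Path(in_dir)
    paths = {}
    for name in TABLE_COLUMNS:
        p = in_dir / f"{name}.csv"
        if p.exists():
            paths[name] = p
        elif name not in OPTIONAL_TABLES:
            raise FileNotFoundError(p)
    return paths
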