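"""Measurement derivation, reliability filtering and covariate construction.

Turns validated EHR tables into one analysis-ready row per reliable LDL-c
measurement in an adult patient with established cardiovascular disease
(a *measurement context*), carrying the covariates used downstream:
demographics, comorbidity flags, medication classes and the statin (type,
daily dose, atorvastatin-20 equivalents) in effect at the measurement date.

Lipid panels missing a direct LDL-c are completed with the Friedewald
formula  LDL = TC - HDL - TG/2.2  (mmol/L convention), which is unreliable
at very low LDL-c and at triglycerides above 8.0 mmol/L; such panels are
excluded (low LDL-c only before the laboratory's remeasurement policy
change).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .ehr_model import CVD_CATEGORIES, CohortConfig

logger = logging.getLogger(__name__)

__all__ = [
    "DerivationError",
    "UnmappedStatinError",
    "ExclusionLog",
    "friedewald_ldl",
    "assemble_panels",
    "apply_reliability_filter",
    "cvd_status_at",
    "classify_medication",
    "hypertension_at",
    "ckd_at",
    "statin_equivalent_dose",
    "load_statin_equivalence",
    "load_cvd_code_map",
    "build_contexts",
]

PANEL_COLUMNS = [
    "patient_id",
    "date",
    "tc",
    "hdl",
    "tg",
    "ldl",
    "ldl_source",
    "reliable",
    "exclusion_reason",
]


class DerivationError(ValueError):
    """Friedewald derivation impossible (an input lipid is missing)."""


class UnmappedStatinError(KeyError):
    """Statin type absent from the equivalence table."""


def load_statin_equivalence() -> dict[str, float]:
    """Default statin potency table: dose (mg/day) equipotent to
    atorvastatin 20 mg/day, per statin type."""
    with resources.files("ldltraj.data").joinpath("statin_equivalence.csv").open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["statin_type"], df["dose_mg_equal_to_atorva20"].astype(float)))


def load_cvd_code_map() -> dict[str, str]:
    """Editable diagnosis/billing code -> category map shipped with the
    package (real coding systems are site-specific)."""
    with resources.files("ldltraj.data").joinpath("cvd_code_map.csv").open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["code"], df["category"]))


# ---------------------------------------------------------------------------
# lipid derivation and filtering
# ---------------------------------------------------------------------------


def friedewald_ldl(tc: float, hdl: float, tg: float) -> float:
    """LDL-c (mmol/L) from total cholesterol, HDL-c and triglycerides.

    Returns ``tc - hdl - tg/2.2``; may be negative (callers filter).
    Raises :class:`DerivationError` if any input is missing.
    """
    if tc is None or hdl is None or tg is None:
        raise DerivationError("Friedewald derivation requires TC, HDL and TG")
    if np.isnan(tc) or np.isnan(hdl) or np.isnan(tg):
        raise DerivationError("Friedewald derivation requires TC, HDL and TG")
    return tc - hdl - tg / 2.2


def assemble_panels(labs: pd.DataFrame) -> pd.DataFrame:
    """Group lab rows into one lipid panel per (patient_id, date).

    A panel is emitted when the date has a direct LDL-c measurement or the
    full TC/HDL/TG triplet; direct LDL-c is preferred when both exist.
    Duplicate analytes on one date keep the first occurrence. Dates with
    insufficient analytes are dropped (count logged).
    """
    lipids = labs[labs["analyte"].isin(["TC", "HDL", "TG", "LDL_direct"])]
    if lipids.empty:
        return pd.DataFrame(columns=PANEL_COLUMNS)
    wide = (
        lipids.drop_duplicates(["patient_id", "date", "analyte"], keep="first")
        .pivot(index=["patient_id", "date"], columns="analyte", values="value")
        .reindex(columns=["TC", "HDL", "TG", "LDL_direct"])
        .reset_index()
    )
    wide.columns.name = None
    has_direct = wide["LDL_direct"].notna()
    has_triplet = wide[["TC", "HDL", "TG"]].notna().all(axis=1)
    emitted = wide[has_direct | has_triplet].copy()
    n_dropped = len(wide) - len(emitted)
    if n_dropped:
        logger.info("assemble_panels: %d dates lacked sufficient analytes", n_dropped)
    derived = emitted["TC"] - emitted["HDL"] - emitted["TG"] / 2.2
    panels = pd.DataFrame(
        {
            "patient_id": emitted["patient_id"],
            "date": emitted["date"],
            "tc": emitted["TC"],
            "hdl": emitted["HDL"],
            "tg": emitted["TG"],
            "ldl": emitted["LDL_direct"].where(emitted["LDL_direct"].notna(), derived),
            "ldl_source": np.where(emitted["LDL_direct"].notna(), "measured", "friedewald"),
            "reliable": True,
            "exclusion_reason": pd.Series([None] * len(emitted), dtype=object),
        }
    )
    return panels.sort_values(["patient_id", "date"], kind="mergesort").reset_index(drop=True)


def apply_reliability_filter(
    panels: pd.DataFrame, config: CohortConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split panels into (retained, excluded) on the reliability rules.

    Excluded iff the LDL-c is below ``low_ldl_cutoff`` and dated before the
    remeasurement-policy date, or the panel is Friedewald-derived with
    triglycerides above ``high_tg_cutoff``.  Each excluded panel carries
    exactly one reason (high-TG checked first).
    """
    if panels.empty:
        return panels.copy(), panels.copy()
    remeasure = pd.Timestamp(config.remeasure_date)
    high_tg = (panels["ldl_source"] == "friedewald") & (panels["tg"] > config.high_tg_cutoff)
    low_ldl = (panels["ldl"] < config.low_ldl_cutoff) & (panels["date"] < remeasure)
    reason = np.where(high_tg, "high_tg", np.where(low_ldl, "low_ldl_pre2017", None))
    excluded = panels[high_tg | low_ldl].copy()
    excluded["reliable"] = False
    excluded["exclusion_reason"] = reason[(high_tg | low_ldl).to_numpy()]
    retained = panels[~(high_tg | low_ldl)].copy()
    return retained.reset_index(drop=True), excluded.reset_index(drop=True)


# ---------------------------------------------------------------------------
# covariates at a measurement date
# ---------------------------------------------------------------------------


def cvd_status_at(
    patient_id: str,
    date,
    diagnoses: pd.DataFrame,
    config: CohortConfig | None = None,
) -> tuple[bool, set[str]]:
    """CVD status at a measurement: any qualifying event (CHD, stroke,
    peripheral artery disease, abdominal aortic aneurysm) dated up to
    ``cvd_window_days`` after the measurement.  The look-ahead admits
    measurements taken during pre-operative screening."""
    config = config or CohortConfig()
    date = pd.Timestamp(date)
    ev = diagnoses[
        (diagnoses["patient_id"] == patient_id)
        & diagnoses["category"].isin(CVD_CATEGORIES)
        & (diagnoses["date"] <= date + pd.Timedelta(days=config.cvd_window_days))
    ]
    cats = set(ev["category"])
    return bool(cats), cats


def classify_medication(atc_code: str):
    """Map an ATC code to a medication class, or ``None``.

    A10* glucose-lowering; B01*/B02A* antithrombotic; C10AA* statin; other
    C10* other lipid-lowering; C02/C03/C07/C08/C09* blood-pressure-lowering.
    """
    if not atc_code:
        raise ValueError("empty ATC code")
    if atc_code.startswith("A10"):
        return "glucose_lowering"
    if atc_code.startswith(("B01", "B02A")):
        return "antithrombotic"
    if atc_code.startswith("C10AA"):
        return "statin"
    if atc_code.startswith("C10"):
        return "other_lipid_lowering"
    if atc_code.startswith(("C02", "C03", "C07", "C08", "C09")):
        return "bp_lowering"
    return None


def hypertension_at(
    patient_id: str,
    date,
    bp: pd.DataFrame | None,
    prescriptions: pd.DataFrame,
    config: CohortConfig | None = None,
) -> bool:
    """Hypertension: nearest blood pressure within +-bp_window_days above
    140/90 (strict), and/or any blood-pressure-lowering prescription
    registered on or before the date."""
    config = config or CohortConfig()
    date = pd.Timestamp(date)
    if bp is not None and len(bp):
        mine = bp[bp["patient_id"] == patient_id].copy()
        if len(mine):
            mine["delta"] = (mine["date"] - date).abs()
            mine = mine[mine["delta"] <= pd.Timedelta(days=config.bp_window_days)]
            if len(mine):
                # nearest reading; ties broken toward the earlier reading
                mine = mine.sort_values(["delta", "date"], kind="mergesort")
                row = mine.iloc[0]
                if row["systolic"] > 140 or row["diastolic"] > 90:
                    return True
    rx = prescriptions[
        (prescriptions["patient_id"] == patient_id)
        & (prescriptions["registration_date"] <= date)
    ]
    return any(classify_medication(c) == "bp_lowering" for c in rx["atc_code"])


def ckd_at(
    patient_id: str,
    date,
    diagnoses: pd.DataFrame,
    labs: pd.DataFrame,
    config: CohortConfig | None = None,
) -> bool:
    """Chronic kidney disease: CKD/dialysis event on or before the date, or
    any eGFR below the threshold within the (+-2 day) lab window."""
    config = config or CohortConfig()
    date = pd.Timestamp(date)
    ev = diagnoses[
        (diagnoses["patient_id"] == patient_id)
        & diagnoses["category"].isin(["CKD", "DIALYSIS"])
        & (diagnoses["date"] <= date)
    ]
    if len(ev):
        return True
    egfr = labs[
        (labs["patient_id"] == patient_id)
        & (labs["analyte"] == "eGFR")
        & ((labs["date"] - date).abs() <= pd.Timedelta(days=config.egfr_window_days))
    ]
    return bool((egfr["value"] < config.egfr_ckd_threshold).any())


def statin_equivalent_dose(
    statin_type: str, daily_dose_mg: float, equivalence: Mapping[str, float] | None = None
) -> float:
    """Dose in atorvastatin-20 equivalents: ``daily_dose_mg`` divided by the
    type's dose equipotent to atorvastatin 20 mg (linear in dose)."""
    equivalence = equivalence if equivalence is not None else load_statin_equivalence()
    if statin_type not in equivalence:
        raise UnmappedStatinError(statin_type)
    if daily_dose_mg is None or not daily_dose_mg > 0:
        raise ValueError("daily_dose_mg must be positive")
    return daily_dose_mg / equivalence[statin_type]


# ---------------------------------------------------------------------------
# context assembly
# ---------------------------------------------------------------------------


@dataclass
class ExclusionLog:
    """Flowchart bookkeeping: how many panels each step removed."""

    input_panels: int = 0
    unreliable: int = 0
    underage: int = 0
    non_cvd: int = 0
    retained: int = 0
    by_reason: dict = field(default_factory=dict)

    def conserves(self) -> bool:
        return self.input_panels == self.unreliable + self.underage + self.non_cvd + self.retained


def _per_patient_min_date(df: pd.DataFrame, mask: pd.Series, date_col: str) -> pd.Series:
    sub = df[mask]
    return sub.groupby("patient_id")[date_col].min()


def build_contexts(
    tables: Mapping[str, pd.DataFrame],
    config: CohortConfig | None = None,
    equivalence: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Assemble measurement contexts for the CVD cohort.

    Returns one row per retained measurement in an adult patient with
    established CVD, with columns: patient_id, date, ldl, ldl_source,
    age_years, female, cvd flags per category, diabetes, hypertension, ckd,
    smoking_current (nullable), statin_type, statin_dose_mg,
    statin_equivalents, and boolean medication-class columns — plus an
    :class:`ExclusionLog` reproducing the selection flowchart.
    """
    config = config or CohortConfig()
    equivalence = equivalence if equivalence is not None else load_statin_equivalence()
    patients = tables["patients"]
    labs = tables["labs"]
    diagnoses = tables["diagnoses"]
    prescriptions = tables["prescriptions"]
    bp = tables.get("bp")
    smoking = tables.get("smoking")

    panels = assemble_panels(labs)
    log = ExclusionLog(input_panels=len(panels))
    retained, excluded = apply_reliability_filter(panels, config)
    log.unreliable = len(excluded)
    log.by_reason = excluded["exclusion_reason"].value_counts().to_dict() if len(excluded) else {}

    ctx = retained.merge(patients, on="patient_id", how="inner")
    # age at measurement, in whole years elapsed
    age_days = (ctx["date"] - ctx["birth_date"]).dt.days
    ctx["age_years"] = age_days / 365.25
    adult = ctx["age_years"] >= 18.0
    log.underage = int((~adult).sum())
    ctx = ctx[adult].copy()

    # CVD: per patient, earliest event date per qualifying category
    window = pd.Timedelta(days=config.cvd_window_days)
    for cat in CVD_CATEGORIES:
        first = _per_patient_min_date(diagnoses, diagnoses["category"] == cat, "date")
        ctx[f"cvd_{cat.lower()}"] = (
            ctx["patient_id"].map(first).notna()
            & (ctx["patient_id"].map(first) <= ctx["date"] + window)
        )
    cvd_cols = [f"cvd_{c.lower()}" for c in CVD_CATEGORIES]
    ctx["cvd"] = ctx[cvd_cols].any(axis=1)
    log.non_cvd = int((~ctx["cvd"]).sum())
    ctx = ctx[ctx["cvd"]].copy()
    log.retained = len(ctx)

    # medication classes in effect (registered on/before the measurement)
    rx = prescriptions.copy()
    rx["med_class"] = [classify_medication(c) for c in rx["atc_code"]]
    for cls in ("statin", "other_lipid_lowering", "bp_lowering", "glucose_lowering", "antithrombotic"):
        first = _per_patient_min_date(rx, rx["med_class"] == cls, "registration_date")
        ctx[f"med_{cls}"] = (
            ctx["patient_id"].map(first).notna() & (ctx["patient_id"].map(first) <= ctx["date"])
        )

    # diabetes: diagnosis/billing code OR glucose-lowering prescription
    first_dm = _per_patient_min_date(diagnoses, diagnoses["category"] == "DIABETES", "date")
    ctx["diabetes"] = (
        ctx["patient_id"].map(first_dm).notna() & (ctx["patient_id"].map(first_dm) <= ctx["date"])
    ) | ctx["med_glucose_lowering"]

    # CKD: code/intervention OR low eGFR near the measurement
    first_ckd = _per_patient_min_date(
        diagnoses, diagnoses["category"].isin(["CKD", "DIALYSIS"]), "date"
    )
    ckd_code = ctx["patient_id"].map(first_ckd).notna() & (
        ctx["patient_id"].map(first_ckd) <= ctx["date"]
    )
    egfr_low = labs[(labs["analyte"] == "eGFR") & (labs["value"] < config.egfr_ckd_threshold)]
    if len(egfr_low):
        hits = ctx[["patient_id", "date"]].reset_index().merge(
            egfr_low[["patient_id", "date"]].rename(columns={"date": "egfr_date"}),
            on="patient_id",
        )
        hits = hits[
            (hits["egfr_date"] - hits["date"]).abs()
            <= pd.Timedelta(days=config.egfr_window_days)
        ]
        ckd_egfr = ctx.index.isin(hits["index"])
    else:
        ckd_egfr = np.zeros(len(ctx), dtype=bool)
    ctx["ckd"] = ckd_code | ckd_egfr

    # hypertension: nearest BP within the window above 140/90, or BP-lowering rx
    ht_bp = np.zeros(len(ctx), dtype=bool)
    if bp is not None and len(bp):
        hits = ctx[["patient_id", "date"]].reset_index().merge(
            bp.rename(columns={"date": "bp_date"}), on="patient_id"
        )
        hits["delta"] = (hits["bp_date"] - hits["date"]).abs()
        hits = hits[hits["delta"] <= pd.Timedelta(days=config.bp_window_days)]
        if len(hits):
            hits = hits.sort_values(["index", "delta", "bp_date"], kind="mergesort")
            nearest = hits.groupby("index").first()
            elevated = nearest[(nearest["systolic"] > 140) | (nearest["diastolic"] > 90)]
            ht_bp = ctx.index.isin(elevated.index)
    ctx["hypertension"] = ht_bp | ctx["med_bp_lowering"]

    # smoking: most recent dated observation on/before the measurement
    if smoking is not None and len(smoking):
        smk = smoking.sort_values(["patient_id", "date"], kind="mergesort")
        ctx = ctx.sort_values(["date", "patient_id"], kind="mergesort")
        merged = pd.merge_asof(
            ctx[["patient_id", "date"]].reset_index().sort_values("date", kind="mergesort"),
            smk.rename(columns={"date": "smk_date"}).sort_values("smk_date", kind="mergesort"),
            left_on="date",
            right_on="smk_date",
            by="patient_id",
            direction="backward",
        ).set_index("index")
        ctx["smoking_current"] = merged["smoking_current"].reindex(ctx.index)
    else:
        ctx["smoking_current"] = pd.Series([pd.NA] * len(ctx), index=ctx.index, dtype=object)

    # statin in effect: most recent statin prescription on/before the date
    statins = rx[rx["med_class"] == "statin"].sort_values(
        ["patient_id", "registration_date"], kind="mergesort"
    )
    ctx["statin_type"] = None
    ctx["statin_dose_mg"] = np.nan
    ctx["statin_equivalents"] = np.nan
    if len(statins):
        merged = pd.merge_asof(
            ctx[["patient_id", "date"]].reset_index().sort_values("date", kind="mergesort"),
            statins[["patient_id", "registration_date", "drug_name", "daily_dose_mg"]]
            .sort_values("registration_date", kind="mergesort"),
            left_on="date",
            right_on="registration_date",
            by="patient_id",
            direction="backward",
        ).set_index("index")
        ctx["statin_type"] = merged["drug_name"].reindex(ctx.index)
        ctx["statin_dose_mg"] = merged["daily_dose_mg"].reindex(ctx.index)
        known = ctx["statin_type"].map(lambda t: equivalence.get(t) if isinstance(t, str) else np.nan)
        ctx["statin_equivalents"] = ctx["statin_dose_mg"] / known.astype(float)
        n_unmapped = int((ctx["statin_type"].notna() & ctx["statin_equivalents"].isna()).sum())
        if n_unmapped:
            logger.warning("build_contexts: %d statin records with unmapped type", n_unmapped)

    ctx["female"] = ctx["sex"] == "female"
    ctx = ctx.sort_values(["patient_id", "date"], kind="mergesort").reset_index(drop=True)
    keep = (
        ["patient_id", "date", "ldl", "ldl_source", "tc", "hdl", "tg", "age_years", "sex", "female"]
        + cvd_cols
        + ["cvd", "diabetes", "hypertension", "ckd", "smoking_current"]
        + ["med_statin", "med_other_lipid_lowering", "med_bp_lowering", "med_glucose_lowering", "med_antithrombotic"]
        + ["statin_type", "statin_dose_mg", "statin_equivalents"]
    )
    logger.info(
        "build_contexts: %d panels -> %d contexts (%d unreliable, %d underage, %d non-CVD)",
        log.input_panels, log.retained, log.unreliable, log.underage, log.non_cvd,
    )
    return ctx[keep], log
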