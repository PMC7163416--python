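"""Favorable/unfavorable change classification, statin-change
categorization, and the deterioration logistic model.

A measurement-pair change is *favorable* when the next measurement is on
target (the LDL-c decreased to, or remained on, target); everything else —
an increase, an off-target decrease, or off-target stability — is
*unfavorable*.  Since the three unfavorable clauses exactly cover "next
state is off target" at the category level, the classification reduces to
the next state alone.

Statin changes between the two measurements of a pair are compared by type
(drug name) and by dose in atorvastatin-20 equivalents; pairs without a
registered statin at both measurements are not evaluable and are excluded
(counted), mirroring the reduced regression n of medication-incomplete
EHR data.
"""

from __future__ import annotations

import enum
import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .ehr_model import CohortConfig
from .preprocess import load_statin_equivalence
from .target_attainment import LdlState, fit_logistic_or

logger = logging.getLogger(__name__)

__all__ = [
    "ChangeLabel",
    "StatinChange",
    "classify_change",
    "classify_statin_change",
    "build_change_pairs",
    "deterioration_logistic",
]


class ChangeLabel(str, enum.Enum):
    FAVORABLE = "FAVORABLE"
    UNFAVORABLE = "UNFAVORABLE"


class StatinChange(str, enum.Enum):
    SAME_DOSE_SAME_TYPE = "SAME_DOSE_SAME_TYPE"
    SAME_DOSE_DIFF_TYPE = "SAME_DOSE_DIFF_TYPE"
    HIGHER_DOSE_SAME_TYPE = "HIGHER_DOSE_SAME_TYPE"
    LOWER_DOSE_SAME_TYPE = "LOWER_DOSE_SAME_TYPE"
    HIGHER_DOSE_DIFF_TYPE = "HIGHER_DOSE_DIFF_TYPE"
    LOWER_DOSE_DIFF_TYPE = "LOWER_DOSE_DIFF_TYPE"


_DOSE_TOL = 1e-9


def classify_change(prev_state: LdlState, next_state: LdlState) -> ChangeLabel:
    """FAVORABLE iff the next state is on target; otherwise UNFAVORABLE."""
    prev_state = LdlState(prev_state)
    next_state = LdlState(next_state)
    return ChangeLabel.FAVORABLE if next_state == LdlState.ON_TARGET else ChangeLabel.UNFAVORABLE


def classify_statin_change(
    prev: tuple[str, float] | None,
    next_: tuple[str, float] | None,
    equivalence: Mapping[str, float] | None = None,
) -> StatinChange | None:
    """Categorize the statin change between two measurements.

    ``prev``/``next_`` are (statin_type, daily_dose_mg) or None when no
    statin was registered at that measurement.  Returns None (not
    evaluable) when either statin is missing or its type is not in the
    equivalence table.  Dose comparison is in atorvastatin-20 equivalents
    with equality tolerance 1e-9.
    """
    if prev is None or next_ is None:
        return None
    equivalence = equivalence if equivalence is not None else load_statin_equivalence()
    (ptype, pdose), (ntype, ndose) = prev, next_
    if ptype not in equivalence or ntype not in equivalence:
        logger.debug("unmapped statin type %r/%r: pair not evaluable", ptype, ntype)
        return None
    peq = pdose / equivalence[ptype]
    neq = ndose / equivalence[ntype]
    same_type = ptype == ntype
    if abs(neq - peq) <= _DOSE_TOL:
        return StatinChange.SAME_DOSE_SAME_TYPE if same_type else StatinChange.SAME_DOSE_DIFF_TYPE
    if neq > peq:
        return StatinChange.HIGHER_DOSE_SAME_TYPE if same_type else StatinChange.HIGHER_DOSE_DIFF_TYPE
    return StatinChange.LOWER_DOSE_SAME_TYPE if same_type else StatinChange.LOWER_DOSE_DIFF_TYPE


def build_change_pairs(
    sequences: pd.DataFrame,
    contexts: pd.DataFrame,
    equivalence: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """One row per consecutive sequence pair with change labels and
    pair-level covariates.

    Covariates (age, comorbidities, medication, statin in effect) are taken
    from the measurement context of each pair member; the statin-change
    category compares the statin at the previous vs the next measurement.
    Columns include ``evaluable`` (statin present and mapped at both ends).
    """
    equivalence = equivalence if equivalence is not None else load_statin_equivalence()
    seq = sequences.sort_values(["patient_id", "seq_index"], kind="mergesort").reset_index(drop=True)
    ctx_cols = [
        "patient_id", "date", "age_years", "female", "diabetes", "hypertension",
        "ckd", "smoking_current", "med_antithrombotic", "statin_type", "statin_dose_mg",
    ]
    merged = seq.merge(contexts[ctx_cols], on=["patient_id", "date"], how="left")
    prev = merged.iloc[:-1].reset_index(drop=True)
    nxt = merged.iloc[1:].reset_index(drop=True)
    pair_mask = (prev["patient_id"] == nxt["patient_id"]) & (
        nxt["seq_index"] == prev["seq_index"] + 1
    )
    prev = prev[pair_mask.to_numpy()].reset_index(drop=True)
    nxt = nxt[pair_mask.to_numpy()].reset_index(drop=True)

    statin_changes = []
    for p_t, p_d, n_t, n_d in zip(
        prev["statin_type"], prev["statin_dose_mg"], nxt["statin_type"], nxt["statin_dose_mg"]
    ):
        p = (p_t, float(p_d)) if isinstance(p_t, str) and p_d == p_d else None
        n = (n_t, float(n_d)) if isinstance(n_t, str) and n_d == n_d else None
        sc = classify_statin_change(p, n, equivalence)
        statin_changes.append(sc.value if sc is not None else None)

    pairs = pd.DataFrame(
        {
            "patient_id": prev["patient_id"],
            "pair_index": nxt["seq_index"],  # index of the pair's second measurement
            "prev_state": prev["state"].astype(int),
            "next_state": nxt["state"].astype(int),
            "follow_up_type": nxt["follow_up_type"],
            "statin_change": statin_changes,
            "age_years": prev["age_years"],
            "female": prev["female"],
            "diabetes": prev["diabetes"],
            "hypertension": prev["hypertension"],
            "smoking_current": prev["smoking_current"],
            "med_antithrombotic": prev["med_antithrombotic"],
        }
    )
    pairs["change_label"] = np.where(
        pairs["next_state"] == int(LdlState.ON_TARGET),
        ChangeLabel.FAVORABLE.value,
        ChangeLabel.UNFAVORABLE.value,
    )
    pairs["evaluable"] = pairs["statin_change"].notna()
    logger.info(
        "build_change_pairs: %d pairs (%d statin-evaluable)",
        len(pairs), int(pairs["evaluable"].sum()),
    )
    return pairs


#: statin-change dummy levels entering the model (reference: same dose, same type)
_STATIN_LEVELS = [
    StatinChange.SAME_DOSE_DIFF_TYPE,
    StatinChange.HIGHER_DOSE_SAME_TYPE,
    StatinChange.LOWER_DOSE_SAME_TYPE,
    StatinChange.HIGHER_DOSE_DIFF_TYPE,
    StatinChange.LOWER_DOSE_DIFF_TYPE,
]


def deterioration_logistic(pairs: pd.DataFrame) -> pd.DataFrame:
    """Logistic model of unfavorable change on pair covariates.

    Outcome: change label unfavorable.  Covariates: age, female sex,
    diabetes, hypertension, current smoking, antithrombotic use, the
    statin-change category (reference: same dose, same type), the
    measurement number, and follow-up type (reference: short-term).  Fit on
    statin-evaluable, complete-case pairs; raises when the reference
    statin-change level is absent.
    """
    df = pairs[pairs["evaluable"]].copy()
    if df.empty:
        raise ValueError("no evaluable pairs (statin missing everywhere)")
    if not (df["statin_change"] == StatinChange.SAME_DOSE_SAME_TYPE.value).any():
        raise ValueError("reference statin-change level (same dose, same type) is empty")
    df["unfavorable"] = (df["change_label"] == ChangeLabel.UNFAVORABLE.value).astype(int)
    for level in _STATIN_LEVELS:
        df[f"statin_{level.value.lower()}"] = (df["statin_change"] == level.value).astype(float)
    df["follow_up_long"] = (df["follow_up_type"] == "LONG").astype(float)
    df["measurement_number"] = df["pair_index"].astype(float)
    for col in ("female", "diabetes", "hypertension", "med_antithrombotic"):
        df[col] = df[col].astype(float)
    df["smoking_current"] = df["smoking_current"].map({True: 1.0, False: 0.0})
    covariates = (
        ["age_years", "female", "diabetes", "hypertension", "smoking_current", "med_antithrombotic"]
        + [f"statin_{l.value.lower()}" for l in _STATIN_LEVELS]
        + ["measurement_number", "follow_up_long"]
    )
    return fit_logistic_or(df, "unfavorable", covariates)
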