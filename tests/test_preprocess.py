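"""Friedewald derivation, reliability filtering and covariate logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldltraj.ehr_model import CohortConfig
from ldltraj.preprocess import (
    DerivationError,
    UnmappedStatinError,
    apply_reliability_filter,
    assemble_panels,
    build_contexts,
    ckd_at,
    classify_medication,
    cvd_status_at,
    friedewald_ldl,
    hypertension_at,
    load_statin_equivalence,
    statin_equivalent_dose,
)


@pytest.mark.parametrize(
    "tc,hdl,tg,expected",
    [(5.0, 1.0, 2.2, 3.0), (4.0, 4.0, 0.0, 0.0), (4.0, 1.0, 8.8, -1.0)],
)
def test_friedewald_values(tc, hdl, tg, expected):
    assert friedewald_ldl(tc, hdl, tg) == pytest.approx(expected, abs=1e-12)


def test_friedewald_missing_input_raises():
    with pytest.raises(DerivationError):
        friedewald_ldl(5.0, np.nan, 2.2)


def test_assemble_panels_rules(labs_frame):
    panels = assemble_panels(labs_frame)
    # C has only TC+HDL: no panel
    assert set(panels["patient_id"]) == {"A", "B"}
    a = panels[panels["patient_id"] == "A"].iloc[0]
    assert a["ldl_source"] == "friedewald"
    assert a["ldl"] == pytest.approx(5.0 - 1.0 - 1.0, abs=1e-12)
    b = panels[panels["patient_id"] == "B"].iloc[0]
    # direct measurement preferred over the derivable triplet
    assert b["ldl_source"] == "measured" and b["ldl"] == 2.0


def test_friedewald_identity_on_generated(small_cohort):
    tables, _ = small_cohort
    panels = assemble_panels(tables["labs"])
    fw = panels[panels["ldl_source"] == "friedewald"]
    assert len(fw) > 0
    np.testing.assert_allclose(
        fw["ldl"] + fw["hdl"] + fw["tg"] / 2.2, fw["tc"], atol=1e-9
    )


def _panel(date, ldl, source="friedewald", tg=1.5):
    return {
        "patient_id": "A", "date": pd.Timestamp(date), "tc": np.nan, "hdl": np.nan,
        "tg": tg, "ldl": ldl, "ldl_source": source, "reliable": True,
        "exclusion_reason": None,
    }


@pytest.mark.parametrize(
    "panel,excluded,reason",
    [
        (_panel("2016-05-01", 0.5), True, "low_ldl_pre2017"),
        (_panel("2017-06-01", 0.5), True, None),  # after remeasurement date: kept
        (_panel("2012-01-01", 2.0, tg=9.0), True, "high_tg"),
        (_panel("2012-01-01", 2.0, source="measured", tg=9.0), False, None),
        (_panel("2012-01-01", 2.0), False, None),
    ],
)
def test_reliability_filter_cases(panel, excluded, reason, config):
    panels = pd.DataFrame([panel])
    retained, dropped = apply_reliability_filter(panels, config)
    if reason is None:
        assert len(retained) == 1 and len(dropped) == 0
    else:
        assert len(dropped) == 1 and dropped.iloc[0]["exclusion_reason"] == reason


def test_filter_conservation_and_single_reason(small_cohort, config):
    tables, _ = small_cohort
    panels = assemble_panels(tables["labs"])
    retained, dropped = apply_reliability_filter(panels, config)
    assert len(retained) + len(dropped) == len(panels)
    assert dropped["exclusion_reason"].isin(["low_ldl_pre2017", "high_tg"]).all()


@given(cutoff=st.floats(min_value=0.5, max_value=20.0))
@settings(deadline=None, max_examples=25)
def test_raising_tg_cutoff_monotone(cutoff):
    """Raising the high-TG cutoff never decreases the retained count."""
    rng = np.random.default_rng(7)
    panels = pd.DataFrame(
        [_panel("2012-01-01", 2.0, tg=float(t)) for t in rng.uniform(0.5, 15, 40)]
    )
    base = CohortConfig(high_tg_cutoff=cutoff)
    higher = CohortConfig(high_tg_cutoff=cutoff + 1.0)
    assert len(apply_reliability_filter(panels, higher)[0]) >= len(
        apply_reliability_filter(panels, base)[0]
    )


def _dx(pid, date, category, code="CHD01"):
    return pd.DataFrame(
        {"patient_id": [pid], "date": [pd.Timestamp(date)], "code": [code],
         "category": [category]}
    )


@pytest.mark.parametrize(
    "event_date,meas_date,expected",
    [
        ("2010-01-01", "2010-06-01", True),   # event precedes measurement
        ("2010-06-04", "2010-06-01", True),   # 3 days after: pre-op screening window
        ("2010-07-01", "2010-06-01", False),  # 30 days after only
    ],
)
def test_cvd_window(event_date, meas_date, expected, config):
    dx = _dx("A", event_date, "CHD")
    cvd, cats = cvd_status_at("A", meas_date, dx, config)
    assert cvd is expected
    assert cats == ({"CHD"} if expected else set())


def test_cvd_monotone_in_date(config):
    """Once CVD is true at a date it stays true at all later dates."""
    dx = _dx("A", "2010-06-04", "CHD")
    dates = pd.date_range("2010-05-20", "2010-08-01", freq="3D")
    flags = [cvd_status_at("A", d, dx, config)[0] for d in dates]
    assert flags == sorted(flags)


@pytest.mark.parametrize(
    "code,expected",
    [
        ("C10AA05", "statin"),
        ("C10AB02", "other_lipid_lowering"),
        ("A10BA02", "glucose_lowering"),
        ("B01AC06", "antithrombotic"),
        ("B02AA01", "antithrombotic"),
        ("C02AB01", "bp_lowering"),
        ("C03CA01", "bp_lowering"),
        ("C07AB02", "bp_lowering"),
        ("C08CA01", "bp_lowering"),
        ("C09AA02", "bp_lowering"),
        ("J01CA04", None),
        ("C01DA02", None),
    ],
)
def test_classify_medication(code, expected):
    assert classify_medication(code) == expected


_EMPTY_RX = pd.DataFrame(columns=["patient_id", "registration_date", "atc_code"])


def _bp(pid, date, sys_, dia):
    return pd.DataFrame(
        {"patient_id": [pid], "date": [pd.Timestamp(date)], "systolic": [sys_],
         "diastolic": [dia]}
    )


def test_hypertension_bp_threshold(config):
    assert hypertension_at("A", "2010-01-01", _bp("A", "2010-01-01", 150, 80), _EMPTY_RX, config)
    assert not hypertension_at("A", "2010-01-01", _bp("A", "2010-01-01", 135, 85), _EMPTY_RX, config)
    # boundary is strict: exactly 140/90 is not hypertensive
    assert not hypertension_at("A", "2010-01-01", _bp("A", "2010-01-01", 140, 90), _EMPTY_RX, config)


def test_hypertension_via_prescription(config):
    rx = pd.DataFrame(
        {"patient_id": ["A"], "registration_date": [pd.Timestamp("2009-01-01")],
         "atc_code": ["C07AB02"]}
    )
    assert hypertension_at("A", "2010-01-01", None, rx, config)
    # no look-ahead: prescription after the date does not count
    assert not hypertension_at("A", "2008-01-01", None, rx, config)


def test_ckd_egfr_window(config):
    labs = pd.DataFrame(
        {"patient_id": ["A"], "date": [pd.Timestamp("2010-01-04")],
         "analyte": ["eGFR"], "value": [45.0]}
    )
    dx = _dx("A", "2000-01-01", "CHD")  # no CKD codes
    assert ckd_at("A", "2010-01-05", dx, labs, config)  # 1 day before, below 60
    assert not ckd_at("A", "2010-01-15", dx, labs, config)  # 11 days: outside window
    assert ckd_at("A", "2010-01-15", _dx("A", "2009-01-01", "DIALYSIS"), labs.iloc[:0], config)


@pytest.mark.parametrize(
    "statin,dose,expected",
    [("atorvastatin", 20, 1.0), ("atorvastatin", 40, 2.0), ("simvastatin", 40, 1.0),
     ("rosuvastatin", 5, 0.5)],
)
def test_statin_equivalents(statin, dose, expected):
    assert statin_equivalent_dose(statin, dose) == pytest.approx(expected)


def test_unmapped_statin_raises():
    with pytest.raises(UnmappedStatinError):
        statin_equivalent_dose("cerivastatin", 10, load_statin_equivalence())


def test_build_contexts_conservation(small_cohort, config):
    tables, truth = small_cohort
    ctx, log = build_contexts(tables, config)
    assert log.conserves()
    assert log.retained == len(ctx)
    # all base-generator panels are reliable adult CVD measurements
    assert log.unreliable == 0 and log.underage == 0 and log.non_cvd == 0


def test_contexts_recover_true_covariates(small_cohort, config):
    tables, truth = small_cohort
    ctx, _ = build_contexts(tables, config)
    per_pat = ctx.groupby("patient_id").first()
    tp = truth.patients.set_index("patient_id").loc[per_pat.index]
    assert (per_pat["female"] == tp["female"]).all()
    assert (per_pat["diabetes"] == tp["diabetes"]).all()
    assert (per_pat["hypertension"] == tp["hypertension"]).all()
    assert (per_pat["ckd"] == tp["ckd"]).all()
    assert (per_pat["smoking_current"].astype(bool) == tp["smoking"]).all()
    assert (per_pat["med_antithrombotic"] == tp["antithrombotic"]).all()
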