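"""LDL-c target categorization, attainment prevalence, and the baseline
off-target logistic model.

States form a 6-level ordinal scale: on target (LDL-c below the guideline
target, default 2.5 mmol/L) or off target by <0.5, 0.5-0.9, 1.0-1.4,
1.5-1.9, or >=2.0 mmol/L.  The off-target bins are half-open intervals of
the distance d = ldl - target: [0,0.5), [0.5,1.0), [1.0,1.5), [1.5,2.0),
[2.0, inf) — exhaustive for continuous values and matching the reported
1-decimal bin labels.
"""

from __future__ import annotations

import enum
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ehr_model import CohortConfig

logger = logging.getLogger(__name__)

__all__ = [
    "LdlState",
    "STATE_LABELS",
    "N_STATES",
    "ldl_state",
    "ldl_states",
    "state_bin_bounds",
    "split_by_repetition",
    "attainment_prevalence",
    "baseline_table",
    "first_measurements",
    "offtarget_logistic",
    "fit_logistic_or",
]


class LdlState(enum.IntEnum):
    """Ordinal LDL-c category relative to the target."""

    ON_TARGET = 0
    OFF_LT_0_5 = 1
    OFF_0_5_0_9 = 2
    OFF_1_0_1_4 = 3
    OFF_1_5_1_9 = 4
    OFF_GE_2_0 = 5


N_STATES = len(LdlState)
STATE_LABELS = [s.name for s in LdlState]

# off-target bin edges for d = ldl - target
_OFF_EDGES = np.array([0.0, 0.5, 1.0, 1.5, 2.0])


def ldl_state(ldl: float, target: float = 2.5) -> LdlState:
    """Categorize a single LDL-c value against the target (strict: on
    target iff ldl < target)."""
    if ldl < 0 or np.isnan(ldl):
        raise ValueError(f"ldl must be a non-negative number, got {ldl}")
    if ldl < target:
        return LdlState.ON_TARGET
    d = ldl - target
    return LdlState(1 + int(np.searchsorted(_OFF_EDGES, d, side="right") - 1))


def ldl_states(ldl: np.ndarray, target: float = 2.5) -> np.ndarray:
    """Vectorized :func:`ldl_state`; returns integer codes."""
    ldl = np.asarray(ldl, dtype=float)
    if np.any(ldl < 0) or np.any(np.isnan(ldl)):
        raise ValueError("ldl values must be non-negative")
    d = ldl - target
    codes = np.searchsorted(_OFF_EDGES, d, side="right")  # 1..5 for d >= 0
    return np.where(ldl < target, 0, codes).astype(int)


def state_bin_bounds(state: LdlState, target: float = 2.5, top_cap: float = 8.0):
    """(low, high) LDL-c interval represented by a state (half-open; the
    top bin is capped for sampling purposes)."""
    if state == LdlState.ON_TARGET:
        return (0.0, target)
    i = int(state) - 1
    low = target + _OFF_EDGES[i]
    high = target + (_OFF_EDGES[i + 1] if i + 1 < len(_OFF_EDGES) else top_cap - target)
    return (float(low), float(high))


# ---------------------------------------------------------------------------
# cohort summaries
# ---------------------------------------------------------------------------


def split_by_repetition(contexts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition patients by measurement count: (single, repeated).

    Returns the contexts of patients with exactly one retained measurement
    and those with two or more."""
    counts = contexts.groupby("patient_id")["date"].transform("size")
    return (
        contexts[counts == 1].reset_index(drop=True),
        contexts[counts >= 2].reset_index(drop=True),
    )


def first_measurements(contexts: pd.DataFrame) -> pd.DataFrame:
    """Earliest retained measurement per patient; same-date ties prefer a
    directly measured LDL-c over a Friedewald-derived one."""
    ctx = contexts.copy()
    ctx["_src_rank"] = (ctx["ldl_source"] != "measured").astype(int)
    ctx = ctx.sort_values(["patient_id", "date", "_src_rank"], kind="mergesort")
    first = ctx.groupby("patient_id", as_index=False).first()
    counts = contexts.groupby("patient_id").size()
    first["repeated"] = first["patient_id"].map(counts).ge(2)
    return first.drop(columns="_src_rank")


def attainment_prevalence(
    contexts: pd.DataFrame,
    grouping: str = "overall",
    config: CohortConfig | None = None,
) -> pd.DataFrame:
    """On-target proportion with numerator/denominator, per group.

    grouping: ``overall``, ``per_year`` (calendar year of the measurement)
    or ``per_stratum`` (single vs repeated measurements, at the first
    measurement per patient).
    """
    config = config or CohortConfig()
    if grouping == "per_stratum":
        df = first_measurements(contexts)
        df["group"] = np.where(df["repeated"], "repeated", "single")
    elif grouping == "per_year":
        df = contexts.copy()
        df["group"] = df["date"].dt.year
    elif grouping == "overall":
        df = contexts.copy()
        df["group"] = "overall"
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    if df.empty:
        logger.info("attainment_prevalence: empty input, no groups emitted")
        return pd.DataFrame(columns=["group", "on_target", "total", "proportion"])
    df["on_target"] = ldl_states(df["ldl"].to_numpy(), config.ldl_target) == 0
    out = (
        df.groupby("group")
        .agg(on_target=("on_target", "sum"), total=("on_target", "size"))
        .reset_index()
    )
    out["proportion"] = out["on_target"] / out["total"]
    return out


def baseline_table(contexts: pd.DataFrame, config: CohortConfig | None = None) -> pd.DataFrame:
    """Descriptive table at first measurement, stratified by repetition.

    Binary traits as n (%), age and blood pressure as mean (SD) when
    available, LDL-c as median (IQR).  SD is reported absent for strata of
    one patient.
    """
    first = first_measurements(contexts)
    rows = []
    for stratum, grp in first.groupby(first["repeated"].map({False: "single", True: "repeated"})):
        n = len(grp)

        def binary(name, series):
            k = int(pd.Series(series).fillna(False).astype(bool).sum())
            rows.append(
                {"stratum": stratum, "characteristic": name, "statistic": "n_pct",
                 "value": k, "spread": 100.0 * k / n if n else np.nan}
            )

        def mean_sd(name, series):
            s = pd.Series(series).dropna().astype(float)
            sd = float(s.std(ddof=1)) if len(s) > 1 else np.nan
            rows.append(
                {"stratum": stratum, "characteristic": name, "statistic": "mean_sd",
                 "value": float(s.mean()) if len(s) else np.nan, "spread": sd}
            )

        rows.append({"stratum": stratum, "characteristic": "n_patients",
                     "statistic": "n", "value": n, "spread": np.nan})
        binary("women", grp["female"])
        mean_sd("age_years", grp["age_years"])
        binary("smoking_current", grp["smoking_current"])
        s = grp["ldl"].astype(float)
        rows.append({"stratum": stratum, "characteristic": "ldl_median", "statistic": "median_iqr",
                     "value": float(s.median()),
                     "spread": float(s.quantile(0.75) - s.quantile(0.25)) if len(s) > 1 else np.nan})
        for trait in ("diabetes", "hypertension", "ckd"):
            binary(trait, grp[trait])
        for cat in ("cvd_chd", "cvd_stroke", "cvd_pad", "cvd_aaa"):
            binary(cat, grp[cat])
        for med in ("med_statin", "med_other_lipid_lowering", "med_bp_lowering",
                    "med_glucose_lowering", "med_antithrombotic"):
            binary(med, grp[med])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic models
# ---------------------------------------------------------------------------


class ModelFitError(RuntimeError):
    """Logistic fit failed (separation, non-convergence, empty class)."""


def fit_logistic_or(
    df: pd.DataFrame, outcome: str, covariates: list[str]
) -> pd.DataFrame:
    """Maximum-likelihood logistic fit; odds ratios with Wald 95% CIs.

    Complete-case: rows with any missing covariate or outcome are dropped.
    Returns a DataFrame indexed by covariate with columns ``or_``,
    ``ci_low``, ``ci_high``, ``coef``, ``se``, ``n``.
    """
    data = df[[outcome] + covariates].apply(pd.to_numeric, errors="coerce").dropna()
    n = len(data)
    y = data[outcome].astype(float)
    if y.nunique() < 2:
        raise ModelFitError("outcome has an empty class after complete-case filtering")
    # covariates without variation (e.g. a stratum-defining indicator in a
    # degenerate cohort) carry no information and break the fit; drop them
    kept = [c for c in covariates if data[c].nunique() > 1]
    dropped = sorted(set(covariates) - set(kept))
    if dropped:
        logger.warning("fit_logistic_or: dropping constant covariates %s", dropped)
    covariates = kept
    if not covariates:
        raise ModelFitError("no covariates with variation")
    X = sm.add_constant(data[covariates].astype(float), has_constant="add")
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise ModelFitError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ModelFitError("logistic fit did not converge (possible separation)")
    ci = res.conf_int(alpha=0.05)
    out = pd.DataFrame(
        {
            "coef": res.params,
            "se": res.bse,
            "or_": np.exp(res.params),
            "ci_low": np.exp(ci[0]),
            "ci_high": np.exp(ci[1]),
        }
    )
    out["n"] = n
    return out.drop(index="const")


BASELINE_COVARIATES = [
    "age_years",
    "female",
    "diabetes",
    "hypertension",
    "ckd",
    "med_statin",
    "med_antithrombotic",
    "smoking_current",
    "repeated",
]


def offtarget_logistic(
    first: pd.DataFrame, config: CohortConfig | None = None,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Factors associated with being off target at the first measurement.

    ``first`` is the output of :func:`first_measurements` (one row per
    patient).  Outcome: state != on target.  Default covariates: age
    (per-year), female sex, diabetes, hypertension, CKD, statin use,
    antithrombotic use, current smoking, and the repeated-measurements
    indicator.
    """
    config = config or CohortConfig()
    covariates = covariates or BASELINE_COVARIATES
    df = first.copy()
    df["off_target"] = (ldl_states(df["ldl"].to_numpy(), config.ldl_target) != 0).astype(int)
    for col in covariates:
        if df[col].dtype == object:
            df[col] = df[col].map({True: 1.0, False: 0.0})
        elif df[col].dtype == bool:
            df[col] = df[col].astype(float)
    return fit_logistic_or(df, "off_target", covariates)
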