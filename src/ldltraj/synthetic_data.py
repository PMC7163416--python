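"""Synthetic EHR cohort generator with known ground truth.

Emulates the data structure of a tertiary-care lipid-management extract:
dated lipid panels (with Friedewald-derivable panels before the
laboratory's remeasurement-policy date and a configurable missing-direct
fraction after it), CVD/diabetes/CKD diagnosis events, ATC-coded
prescriptions with statin doses, blood pressure and smoking observations,
and irregular inter-measurement intervals spanning the short/long/unrelated
follow-up regimes.

Ground-truth structure:

* Baseline off-target status follows a logistic model in the patient
  covariates (defaults: literature-reported odds ratios for first-measurement
  off-target status — women 1.48, diabetes 0.69, hypertension 0.87,
  smoking 1.29, ...).
* State trajectories over related follow-ups follow, by default, a
  time-homogeneous 6-state Markov chain (default matrix: literature-derived
  category-transition probabilities, row-normalized; its largest diagonal
  entry is 0.84).  The alternative ``deterioration`` trajectory model draws
  each related step's favorable/unfavorable outcome from a marginal
  logistic in the pair covariates (defaults: women 1.44, diabetes 0.72,
  statin-change categories, ...), then places unfavorable steps among the
  off-target states proportionally to the chain row.  The marginal form is
  deliberate: the downstream deterioration regression does not adjust for
  the previous state, and a previous-state offset in the generator would
  make that regression misspecified.
* Every mechanism is seeded; identical configs and seeds give identical
  tables.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .ehr_model import CohortConfig, validate_tables
from .target_attainment import LdlState, N_STATES, state_bin_bounds

logger = logging.getLogger(__name__)

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "default_transition_matrix",
    "stationary_distribution",
    "generate_cohort",
    "simulate_state_sequences",
    "sequences_frame",
    "inject_pathologies",
    "expected_estimates",
    "sample_baseline_replicate",
    "sample_deterioration_replicate",
]


def default_transition_matrix() -> np.ndarray:
    """The packaged default 6x6 transition matrix, row-normalized.

    The source values are rounded to two decimals, so some rows sum to
    0.99 or 1.01;
    normalization preserves the exact 0.84 on-target diagonal because that
    row already sums to one.
    """
    with resources.files("ldltraj.data").joinpath("default_transition_matrix.csv").open() as fh:
        df = pd.read_csv(fh, index_col=0)
    m = df.to_numpy(dtype=float)
    return m / m.sum(axis=1, keepdims=True)


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector
    for eigenvalue 1, normalized)."""
    w, v = np.linalg.eig(matrix.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


_LN = np.log

_DEFAULT_BASELINE_COEFS = {
    "age_years": _LN(0.99),  # per year, centered at the mean age internally
    "female": _LN(1.48),
    "diabetes": _LN(0.69),
    "hypertension": _LN(0.87),
    "ckd": _LN(0.75),
    "statin": _LN(0.86),
    "antithrombotic": _LN(0.98),
    "smoking": _LN(1.29),
    "repeated": _LN(1.25),
}

_DEFAULT_DETERIORATION_COEFS = {
    "age_years": _LN(0.99),
    "female": _LN(1.44),
    "diabetes": _LN(0.72),
    "hypertension": _LN(0.93),
    "smoking": 0.0,
    "antithrombotic": _LN(0.81),
    "statin_same_dose_diff_type": _LN(0.81),
    "statin_higher_dose_same_type": _LN(1.82),
    "statin_lower_dose_same_type": _LN(1.31),
    "statin_higher_dose_diff_type": _LN(1.47),
    "statin_lower_dose_diff_type": _LN(0.92),
    "measurement_number": _LN(0.98),
    "follow_up_long": _LN(0.97),
}

_DEFAULT_PREVALENCES = {
    "female": 0.31,
    "diabetes": 0.12,
    "hypertension": 0.33,
    "ckd": 0.01,
    "smoking": 0.10,
    "statin": 0.33,
    "antithrombotic": 0.42,
}

#: statin catalog: type -> (ATC code, daily dose in mg equipotent to
#: atorvastatin 20 mg)
_STATIN_CATALOG = {
    "atorvastatin": ("C10AA05", 20.0),
    "simvastatin": ("C10AA01", 40.0),
    "rosuvastatin": ("C10AA07", 10.0),
    "pravastatin": ("C10AA03", 80.0),
    "fluvastatin": ("C10AA04", 80.0),
}
_STATIN_TYPES = list(_STATIN_CATALOG)
_STATIN_TYPE_WEIGHTS = np.array([0.35, 0.30, 0.15, 0.12, 0.08])

_STATIN_CHANGE_LEVELS = [
    "SAME_DOSE_SAME_TYPE",
    "SAME_DOSE_DIFF_TYPE",
    "HIGHER_DOSE_SAME_TYPE",
    "LOWER_DOSE_SAME_TYPE",
    "HIGHER_DOSE_DIFF_TYPE",
    "LOWER_DOSE_DIFF_TYPE",
]
_DEFAULT_STATIN_CHANGE_PROBS = {
    "SAME_DOSE_SAME_TYPE": 0.80,
    "SAME_DOSE_DIFF_TYPE": 0.04,
    "HIGHER_DOSE_SAME_TYPE": 0.05,
    "LOWER_DOSE_SAME_TYPE": 0.03,
    "HIGHER_DOSE_DIFF_TYPE": 0.05,
    "LOWER_DOSE_DIFF_TYPE": 0.03,
}

#: follow-up interval mixture: weight and day range per regime.  Weights
#: put ~24% of draws in the unrelated (too-soon / too-late) regimes.
_DEFAULT_INTERVAL_MIXTURE = {
    "too_soon": (0.10, 7, 60),
    "short": (0.42, 61, 183),
    "long": (0.34, 184, 548),
    "too_late": (0.14, 549, 900),
}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort, with the study conditions as
    defaults."""

    n_patients: int = 1000
    seed: int = 0
    transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    #: initial distribution over the 6 states; default: the chain's
    #: stationary distribution.  The on/off split is governed by the
    #: baseline logistic; this distribution allocates the off-target mass.
    initial_state_distribution: np.ndarray | None = None
    single_measurement_fraction: float = 0.55
    interval_mixture: dict = field(default_factory=lambda: dict(_DEFAULT_INTERVAL_MIXTURE))
    baseline_intercept: float = 0.04
    baseline_coefficients: dict = field(default_factory=lambda: dict(_DEFAULT_BASELINE_COEFS))
    deterioration_intercept: float = 0.27
    deterioration_coefficients: dict = field(
        default_factory=lambda: dict(_DEFAULT_DETERIORATION_COEFS)
    )
    covariate_prevalences: dict = field(default_factory=lambda: dict(_DEFAULT_PREVALENCES))
    #: "markov": states follow the transition matrix; "deterioration":
    #: favorable/unfavorable outcomes follow the marginal logistic
    trajectory_model: str = "markov"
    missing_direct_ldl_fraction: float = 0.3
    statin_change_probs: dict = field(default_factory=lambda: dict(_DEFAULT_STATIN_CHANGE_PROBS))
    #: extra measurements for repeated patients: 1 + Geometric(p), capped
    followup_geometric_p: float = 0.30
    max_measurements: int = 20
    age_mean: float = 63.0
    age_sd: float = 12.0
    age_min: float = 25.0
    age_max: float = 90.0
    study_start: dt.date = dt.date(2003, 3, 1)
    last_first_date: dt.date = dt.date(2014, 12, 31)
    ldl_target: float = 2.5
    #: lowest LDL-c the base generator emits for on-target states; kept
    #: above the reliability cutoff so only injected panels are unreliable
    on_target_ldl_floor: float = 0.9
    ldl_top_cap: float = 8.0
    remeasure_date: dt.date = dt.date(2017, 1, 24)

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=float)
        if self.transition_matrix.shape != (N_STATES, N_STATES):
            raise ValueError(f"transition_matrix must be {N_STATES}x{N_STATES}")
        if np.any(self.transition_matrix < 0):
            raise ValueError("transition_matrix entries must be non-negative")
        if not np.allclose(self.transition_matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition_matrix rows must sum to 1 (within 1e-9)")
        if self.initial_state_distribution is None:
            self.initial_state_distribution = stationary_distribution(self.transition_matrix)
        self.initial_state_distribution = np.asarray(self.initial_state_distribution, float)
        if not np.isclose(self.initial_state_distribution.sum(), 1.0, atol=1e-9):
            raise ValueError("initial_state_distribution must sum to 1")
        for name in ("single_measurement_fraction", "missing_direct_ldl_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name, p in self.covariate_prevalences.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence of {name!r} must be in [0, 1]")
        w = sum(v[0] for v in self.interval_mixture.values())
        if not np.isclose(w, 1.0, atol=1e-9):
            raise ValueError("interval mixture weights must sum to 1")
        if not np.isclose(sum(self.statin_change_probs.values()), 1.0, atol=1e-9):
            raise ValueError("statin change probabilities must sum to 1")
        if self.trajectory_model not in ("markov", "deterioration"):
            raise ValueError("trajectory_model must be 'markov' or 'deterioration'")


@dataclass
class SyntheticTruth:
    """Everything needed to predict what the pipeline should estimate."""

    config: GeneratorConfig
    patients: pd.DataFrame  # per-patient latent covariates and assignments
    measurements: pd.DataFrame  # per-measurement latent state and linkage
    injected: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        cfg = dataclasses.asdict(self.config)
        cfg["transition_matrix"] = self.config.transition_matrix.tolist()
        cfg["initial_state_distribution"] = self.config.initial_state_distribution.tolist()
        for k in ("study_start", "last_first_date", "remeasure_date"):
            cfg[k] = cfg[k].isoformat()
        payload = {
            "config": cfg,
            "injected": self.injected,
            "n_patients": int(len(self.patients)),
            "n_measurements": int(len(self.measurements)),
        }
        Path(path).write_text(json.dumps(payload, indent=2, default=float))


# ---------------------------------------------------------------------------
# state-sequence simulation (the Markov core)
# ---------------------------------------------------------------------------


def simulate_state_sequences(
    matrix: np.ndarray,
    lengths: np.ndarray,
    rng: np.random.Generator,
    initial: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Simulate integer state sequences from a row-stochastic matrix.

    ``lengths`` gives each sequence's length (>= 1).  ``initial`` is either
    a distribution over states (drawn iid) or None for the stationary
    distribution.
    """
    matrix = np.asarray(matrix, dtype=float)
    lengths = np.asarray(lengths, dtype=int)
    if initial is None:
        initial = stationary_distribution(matrix)
    initial = np.asarray(initial, dtype=float)
    n = len(lengths)
    max_len = int(lengths.max())
    cum = np.cumsum(matrix, axis=1)
    states = np.empty((n, max_len), dtype=int)
    states[:, 0] = rng.choice(len(initial), size=n, p=initial)
    for t in range(1, max_len):
        u = rng.random(n)
        states[:, t] = (u[:, None] > cum[states[:, t - 1]]).sum(axis=1)
    return [states[i, : lengths[i]] for i in range(n)]


def sequences_frame(arrays: list[np.ndarray]) -> pd.DataFrame:
    """Wrap raw state arrays in the long sequence format used by the
    trajectory stage (synthetic ids, daily index spacing irrelevant)."""
    rows = []
    for i, arr in enumerate(arrays):
        for j, s in enumerate(arr, start=1):
            rows.append((f"S{i:07d}", j, pd.NaT, np.nan, int(s),
                         None if j == 1 else "SHORT"))
    return pd.DataFrame(
        rows, columns=["patient_id", "seq_index", "date", "ldl", "state", "follow_up_type"]
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


def _ldl_for_state(state: int, cfg: GeneratorConfig, rng: np.random.Generator) -> float:
    low, high = state_bin_bounds(LdlState(state), cfg.ldl_target, cfg.ldl_top_cap)
    if state == 0:
        low = cfg.on_target_ldl_floor
    return float(rng.uniform(low, high))


def _age_years(date: dt.date, birth: dt.date) -> float:
    return (date - birth).days / 365.25


def generate_cohort(cfg: GeneratorConfig) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Generate the six EHR tables plus ground truth. Deterministic given
    the config seed."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    prev = cfg.covariate_prevalences

    female = rng.random(n) < prev["female"]
    diabetes = rng.random(n) < prev["diabetes"]
    hypertension = rng.random(n) < prev["hypertension"]
    ckd = rng.random(n) < prev["ckd"]
    smoking = rng.random(n) < prev["smoking"]
    statin = rng.random(n) < prev["statin"]
    antithrombotic = rng.random(n) < prev["antithrombotic"]
    single = rng.random(n) < cfg.single_measurement_fraction
    n_extra = np.where(
        single, 0,
        np.minimum(rng.geometric(cfg.followup_geometric_p, n), cfg.max_measurements - 1),
    )
    age_draw = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), cfg.age_min, cfg.age_max)
    first_span = (cfg.last_first_date - cfg.study_start).days
    first_offsets = rng.integers(0, first_span + 1, n)

    start = pd.Timestamp(cfg.study_start)
    first_dates = np.array([start + pd.Timedelta(days=int(o)) for o in first_offsets])
    birth_dates = np.array(
        [fd - pd.Timedelta(days=int(round(a * 365.25))) for fd, a in zip(first_dates, age_draw)]
    )
    age_real = np.array([_age_years(fd.date(), bd.date()) for fd, bd in zip(first_dates, birth_dates)])

    # baseline off-target logistic (age centered at the configured mean so
    # the intercept calibrates the marginal prevalence)
    b = cfg.baseline_coefficients
    lp = (
        cfg.baseline_intercept
        + b["age_years"] * (age_real - cfg.age_mean)
        + b["female"] * female
        + b["diabetes"] * diabetes
        + b["hypertension"] * hypertension
        + b["ckd"] * ckd
        + b["statin"] * statin
        + b["antithrombotic"] * antithrombotic
        + b["smoking"] * smoking
        + b["repeated"] * (~single)
    )
    p_off = expit(lp)
    off_baseline = rng.random(n) < p_off
    init = cfg.initial_state_distribution
    off_mass = init[1:].sum()
    # degenerate initial distributions (all mass on target) still need an
    # off-state allocation for baseline-off patients: fall back to uniform
    off_dist = init[1:] / off_mass if off_mass > 0 else np.full(N_STATES - 1, 1 / (N_STATES - 1))
    off_states = rng.choice(np.arange(1, N_STATES), size=n, p=off_dist)
    baseline_state = np.where(off_baseline, off_states, 0)

    mix_names = list(cfg.interval_mixture)
    mix_w = np.array([cfg.interval_mixture[k][0] for k in mix_names])
    sc_names = _STATIN_CHANGE_LEVELS
    sc_w = np.array([cfg.statin_change_probs[k] for k in sc_names])
    det = cfg.deterioration_coefficients
    remeasure = pd.Timestamp(cfg.remeasure_date)
    P = cfg.transition_matrix
    row_off = P[:, 1:] / P[:, 1:].sum(axis=1, keepdims=True)

    pat_rows, lab_rows, dx_rows, rx_rows, bp_rows, smk_rows = [], [], [], [], [], []
    meas_rows = []

    cvd_cats = rng.choice(
        ["CHD", "STROKE", "PAD", "AAA"], size=n, p=[0.66, 0.18, 0.12, 0.04]
    )
    cvd_codes = {"CHD": "CHD01", "STROKE": "STR01", "PAD": "PAD01", "AAA": "AAA01"}

    def emit_labs(pid, date, ldl):
        if date < remeasure or rng.random() < cfg.missing_direct_ldl_fraction:
            hdl = rng.uniform(0.8, 1.8)
            tg = rng.uniform(0.8, 2.5)
            lab_rows.append((pid, date, "TC", ldl + hdl + tg / 2.2))
            lab_rows.append((pid, date, "HDL", hdl))
            lab_rows.append((pid, date, "TG", tg))
        else:
            lab_rows.append((pid, date, "LDL_direct", ldl))

    for i in range(n):
        pid = f"P{i:06d}"
        fd = first_dates[i]
        pat_rows.append((pid, "female" if female[i] else "male", birth_dates[i]))
        dx_rows.append(
            (pid, fd - pd.Timedelta(days=int(rng.integers(30, 1500))),
             cvd_codes[cvd_cats[i]], cvd_cats[i])
        )
        if diabetes[i]:
            dx_rows.append((pid, fd - pd.Timedelta(days=int(rng.integers(30, 2000))), "DM01", "DIABETES"))
            if rng.random() < 0.6:
                rx_rows.append((pid, fd - pd.Timedelta(days=int(rng.integers(10, 400))),
                                "A10BA02", "metformin", np.nan))
        if ckd[i]:
            dx_rows.append((pid, fd - pd.Timedelta(days=int(rng.integers(30, 2000))), "CKD01", "CKD"))
        if hypertension[i]:
            rx_rows.append((pid, fd - pd.Timedelta(days=int(rng.integers(10, 400))),
                            "C07AB02", "metoprolol", np.nan))
        if antithrombotic[i]:
            rx_rows.append((pid, fd - pd.Timedelta(days=int(rng.integers(10, 400))),
                            "B01AC06", "acetylsalicylic acid", np.nan))
        smk_rows.append((pid, fd, bool(smoking[i])))
        if hypertension[i]:
            sys_ = float(np.clip(rng.normal(148, 12), 110, 210))
            dia = float(min(np.clip(rng.normal(88, 9), 60, 120), sys_ - 5))
        else:
            sys_ = float(np.clip(rng.normal(128, 9), 100, 139))
            dia = float(min(np.clip(rng.normal(78, 6), 55, 89), sys_ - 5))
        bp_rows.append((pid, fd, sys_, dia))

        cur_type = cur_dose = cur_eq = None
        if statin[i]:
            cur_type = _STATIN_TYPES[rng.choice(len(_STATIN_TYPES), p=_STATIN_TYPE_WEIGHTS)]
            cur_eq = float(rng.choice([0.5, 1.0, 2.0], p=[0.25, 0.5, 0.25]))
            cur_dose = cur_eq * _STATIN_CATALOG[cur_type][1]
            rx_rows.append((pid, fd - pd.Timedelta(days=int(rng.integers(10, 300))),
                            _STATIN_CATALOG[cur_type][0], cur_type, cur_dose))

        state = int(baseline_state[i])
        ldl = _ldl_for_state(state, cfg, rng)
        emit_labs(pid, fd, ldl)
        meas_rows.append((pid, fd, state, True, 1, None))

        anchor_date, anchor_state = fd, state
        last_date = fd
        seq_pos = 1
        for _ in range(int(n_extra[i])):
            regime = mix_names[rng.choice(len(mix_names), p=mix_w)]
            lo, hi = cfg.interval_mixture[regime][1:]
            date = last_date + pd.Timedelta(days=int(rng.integers(lo, hi + 1)))
            delta = (date - anchor_date).days
            # classify against the default analysis windows the generator
            # targets; the pipeline re-derives this from its own config
            if delta < 61 or delta > 548:
                ftype = "UNRELATED"
            elif delta <= 183:
                ftype = "SHORT"
            else:
                ftype = "LONG"
            if ftype == "UNRELATED":
                nxt = int(rng.choice(N_STATES, p=P[anchor_state]))
                ldl = _ldl_for_state(nxt, cfg, rng)
                emit_labs(pid, date, ldl)
                meas_rows.append((pid, date, nxt, False, None, "UNRELATED"))
                last_date = date
                continue
            seq_pos += 1
            sc = "SAME_DOSE_SAME_TYPE"
            if cur_type is not None:
                sc = sc_names[rng.choice(len(sc_names), p=sc_w)]
                if sc != "SAME_DOSE_SAME_TYPE":
                    new_type, new_eq = cur_type, cur_eq
                    if "DIFF_TYPE" in sc:
                        others = [t for t in _STATIN_TYPES if t != cur_type]
                        new_type = others[int(rng.integers(len(others)))]
                    if sc.startswith("HIGHER"):
                        new_eq = cur_eq * 2.0
                    elif sc.startswith("LOWER"):
                        new_eq = cur_eq * 0.5
                    cur_type, cur_eq = new_type, new_eq
                    cur_dose = cur_eq * _STATIN_CATALOG[cur_type][1]
                    rx_date = anchor_date + pd.Timedelta(days=max(1, delta // 2))
                    rx_rows.append((pid, rx_date, _STATIN_CATALOG[cur_type][0], cur_type, cur_dose))
            if cfg.trajectory_model == "markov":
                nxt = int(rng.choice(N_STATES, p=P[anchor_state]))
            else:
                age_prev = _age_years(anchor_date.date(), birth_dates[i].date())
                lp_pair = (
                    cfg.deterioration_intercept
                    + det["age_years"] * (age_prev - cfg.age_mean)
                    + det["female"] * female[i]
                    + det["diabetes"] * diabetes[i]
                    + det["hypertension"] * hypertension[i]
                    + det["smoking"] * smoking[i]
                    + det["antithrombotic"] * antithrombotic[i]
                    + det["measurement_number"] * seq_pos
                    + det["follow_up_long"] * (ftype == "LONG")
                )
                if cur_type is not None and sc != "SAME_DOSE_SAME_TYPE":
                    lp_pair += det[f"statin_{sc.lower()}"]
                if rng.random() < expit(lp_pair):  # unfavorable
                    nxt = int(1 + rng.choice(N_STATES - 1, p=row_off[anchor_state]))
                else:
                    nxt = 0
            ldl = _ldl_for_state(nxt, cfg, rng)
            emit_labs(pid, date, ldl)
            meas_rows.append((pid, date, nxt, True, seq_pos, ftype))
            anchor_date, anchor_state = date, nxt
            last_date = date

    tables = {
        "patients": pd.DataFrame(pat_rows, columns=["patient_id", "sex", "birth_date"]),
        "labs": pd.DataFrame(lab_rows, columns=["patient_id", "date", "analyte", "value"]),
        "diagnoses": pd.DataFrame(dx_rows, columns=["patient_id", "date", "code", "category"]),
        "prescriptions": pd.DataFrame(
            rx_rows,
            columns=["patient_id", "registration_date", "atc_code", "drug_name", "daily_dose_mg"],
        ),
        "bp": pd.DataFrame(bp_rows, columns=["patient_id", "date", "systolic", "diastolic"]),
        "smoking": pd.DataFrame(smk_rows, columns=["patient_id", "date", "smoking_current"]),
    }
    truth_patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "female": female,
            "age_first": age_real,
            "diabetes": diabetes,
            "hypertension": hypertension,
            "ckd": ckd,
            "smoking": smoking,
            "statin": statin,
            "antithrombotic": antithrombotic,
            "single": single,
            "n_measurements": 1 + n_extra,
            "p_off_baseline": p_off,
            "off_baseline": off_baseline,
            "baseline_state": baseline_state,
        }
    )
    truth_meas = pd.DataFrame(
        meas_rows,
        columns=["patient_id", "date", "state", "related", "seq_index", "follow_up_type"],
    )
    truth = SyntheticTruth(config=cfg, patients=truth_patients, measurements=truth_meas)
    logger.info("generate_cohort: %d patients, %d measurements", n, len(truth_meas))
    return tables, truth


# ---------------------------------------------------------------------------
# pathology injection
# ---------------------------------------------------------------------------


def inject_pathologies(
    tables: dict[str, pd.DataFrame],
    truth: SyntheticTruth,
    n_low_ldl_pre2017: int = 0,
    n_high_tg: int = 0,
    n_under18: int = 0,
    n_non_cvd: int = 0,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Append records that must be excluded downstream, one fresh patient
    per injection so each maps to exactly one exclusion bucket."""
    rng = rng or np.random.default_rng(truth.config.seed + 1)
    tables = {k: v.copy() for k, v in tables.items()}
    pat, lab, dx = [], [], []
    counter = 0

    def new_pid():
        nonlocal counter
        counter += 1
        return f"X{counter:06d}"

    def add_patient(pid, age, with_cvd, date):
        birth = date - pd.Timedelta(days=int(round(age * 365.25)))
        pat.append((pid, "male", birth))
        if with_cvd:
            dx.append((pid, date - pd.Timedelta(days=100), "CHD01", "CHD"))

    for _ in range(n_low_ldl_pre2017):
        pid = new_pid()
        date = pd.Timestamp("2010-06-15") + pd.Timedelta(days=int(rng.integers(0, 365)))
        add_patient(pid, 60.0, True, date)
        ldl = float(rng.uniform(0.2, 0.7))
        hdl, tg = 1.2, 1.5
        lab.append((pid, date, "TC", ldl + hdl + tg / 2.2))
        lab.append((pid, date, "HDL", hdl))
        lab.append((pid, date, "TG", tg))
    for _ in range(n_high_tg):
        pid = new_pid()
        date = pd.Timestamp("2012-06-15") + pd.Timedelta(days=int(rng.integers(0, 365)))
        add_patient(pid, 60.0, True, date)
        ldl = float(rng.uniform(1.0, 3.0))
        hdl, tg = 1.2, float(rng.uniform(8.5, 12.0))
        lab.append((pid, date, "TC", ldl + hdl + tg / 2.2))
        lab.append((pid, date, "HDL", hdl))
        lab.append((pid, date, "TG", tg))
    for _ in range(n_under18):
        pid = new_pid()
        date = pd.Timestamp("2013-06-15") + pd.Timedelta(days=int(rng.integers(0, 365)))
        add_patient(pid, 15.0, True, date)
        lab.append((pid, date, "TC", 4.0))
        lab.append((pid, date, "HDL", 1.2))
        lab.append((pid, date, "TG", 1.5))
    for _ in range(n_non_cvd):
        pid = new_pid()
        date = pd.Timestamp("2014-06-15") + pd.Timedelta(days=int(rng.integers(0, 365)))
        add_patient(pid, 60.0, False, date)
        lab.append((pid, date, "TC", 4.0))
        lab.append((pid, date, "HDL", 1.2))
        lab.append((pid, date, "TG", 1.5))

    tables["patients"] = pd.concat(
        [tables["patients"], pd.DataFrame(pat, columns=["patient_id", "sex", "birth_date"])],
        ignore_index=True,
    )
    tables["labs"] = pd.concat(
        [tables["labs"], pd.DataFrame(lab, columns=["patient_id", "date", "analyte", "value"])],
        ignore_index=True,
    )
    tables["diagnoses"] = pd.concat(
        [tables["diagnoses"], pd.DataFrame(dx, columns=["patient_id", "date", "code", "category"])],
        ignore_index=True,
    )
    truth.injected = {
        "low_ldl_pre2017": n_low_ldl_pre2017,
        "high_tg": n_high_tg,
        "under18": n_under18,
        "non_cvd": n_non_cvd,
    }
    return tables


# ---------------------------------------------------------------------------
# oracle side
# ---------------------------------------------------------------------------


def expected_estimates(truth: SyntheticTruth) -> dict:
    """What the pipeline should recover, with the quantities that have a
    closed form computed from the configuration."""
    cfg = truth.config
    pi = stationary_distribution(cfg.transition_matrix)
    out = {
        "transition_matrix": cfg.transition_matrix,
        "stationary_distribution": pi,
        "expected_deterioration_rate_markov": float(1.0 - pi @ cfg.transition_matrix[:, 0]),
        "baseline_or": {k: float(np.exp(v)) for k, v in cfg.baseline_coefficients.items()},
        "deterioration_or": {
            k: float(np.exp(v)) for k, v in cfg.deterioration_coefficients.items()
        },
        "single_measurement_fraction": cfg.single_measurement_fraction,
        "expected_off_target_prevalence_first": float(truth.patients["p_off_baseline"].mean()),
        "expected_exclusions": dict(truth.injected),
    }
    return out


# ---------------------------------------------------------------------------
# fast model-level replicate samplers (for seeded recovery studies)
# ---------------------------------------------------------------------------


def sample_baseline_replicate(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw one cohort of first measurements directly at the model level.

    Returns a frame shaped like the first-measurement contexts (columns
    needed by the baseline off-target regression), with the outcome encoded
    in the LDL-c value.  Used for many-replicate CI-coverage studies where
    serializing full EHR tables per replicate adds nothing.
    """
    n = cfg.n_patients
    prev = cfg.covariate_prevalences
    cols = {k: rng.random(n) < p for k, p in prev.items()}
    single = rng.random(n) < cfg.single_measurement_fraction
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n), cfg.age_min, cfg.age_max)
    b = cfg.baseline_coefficients
    lp = (
        cfg.baseline_intercept
        + b["age_years"] * (age - cfg.age_mean)
        + b["female"] * cols["female"]
        + b["diabetes"] * cols["diabetes"]
        + b["hypertension"] * cols["hypertension"]
        + b["ckd"] * cols["ckd"]
        + b["statin"] * cols["statin"]
        + b["antithrombotic"] * cols["antithrombotic"]
        + b["smoking"] * cols["smoking"]
        + b["repeated"] * (~single)
    )
    off = rng.random(n) < expit(lp)
    ldl = np.where(off, rng.uniform(2.6, 4.0, n), rng.uniform(1.5, 2.4, n))
    return pd.DataFrame(
        {
            "patient_id": [f"R{i:06d}" for i in range(n)],
            "ldl": ldl,
            "age_years": age,
            "female": cols["female"],
            "diabetes": cols["diabetes"],
            "hypertension": cols["hypertension"],
            "ckd": cols["ckd"],
            "med_statin": cols["statin"],
            "med_antithrombotic": cols["antithrombotic"],
            "smoking_current": cols["smoking"],
            "repeated": ~single,
        }
    )


def sample_deterioration_replicate(cfg: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw statin-evaluable measurement pairs directly at the model level.

    Mirrors the ``deterioration`` trajectory model for the subset of pairs
    that enter the regression (repeated patients on a registered statin);
    returns a frame shaped like the change-pair table.
    """
    n = cfg.n_patients
    prev = cfg.covariate_prevalences
    keep = (rng.random(n) >= cfg.single_measurement_fraction) & (rng.random(n) < prev["statin"])
    m = int(keep.sum())
    female = rng.random(m) < prev["female"]
    diabetes = rng.random(m) < prev["diabetes"]
    hypertension = rng.random(m) < prev["hypertension"]
    smoking = rng.random(m) < prev["smoking"]
    antithrombotic = rng.random(m) < prev["antithrombotic"]
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, m), cfg.age_min, cfg.age_max)
    lengths = np.minimum(1 + rng.geometric(cfg.followup_geometric_p, m), 6)
    det = cfg.deterioration_coefficients
    sc_w = np.array([cfg.statin_change_probs[k] for k in _STATIN_CHANGE_LEVELS])
    mix = cfg.interval_mixture
    p_long = mix["long"][0] / (mix["short"][0] + mix["long"][0])

    # expand patients to one row per pair (pair_no runs 2..length)
    n_pairs = lengths - 1
    idx = np.repeat(np.arange(m), n_pairs)
    pair_no = np.concatenate([np.arange(2, L + 1) for L in lengths]) if m else np.array([], int)
    sc_codes = rng.choice(len(_STATIN_CHANGE_LEVELS), size=len(idx), p=sc_w)
    sc_coef = np.array(
        [0.0] + [det[f"statin_{lvl.lower()}"] for lvl in _STATIN_CHANGE_LEVELS[1:]]
    )
    long_fu = rng.random(len(idx)) < p_long
    lp = (
        cfg.deterioration_intercept
        + det["age_years"] * (age[idx] - cfg.age_mean)
        + det["female"] * female[idx]
        + det["diabetes"] * diabetes[idx]
        + det["hypertension"] * hypertension[idx]
        + det["smoking"] * smoking[idx]
        + det["antithrombotic"] * antithrombotic[idx]
        + det["measurement_number"] * pair_no
        + det["follow_up_long"] * long_fu
        + sc_coef[sc_codes]
    )
    unfav = rng.random(len(idx)) < expit(lp)
    levels = np.array(_STATIN_CHANGE_LEVELS)
    return pd.DataFrame(
        {
            "patient_id": np.char.add("R", np.char.zfill(idx.astype(str), 6)),
            "pair_index": pair_no,
            "prev_state": 3,
            "next_state": np.where(unfav, 3, 0),
            "follow_up_type": np.where(long_fu, "LONG", "SHORT"),
            "statin_change": levels[sc_codes],
            "age_years": age[idx],
            "female": female[idx],
            "diabetes": diabetes[idx],
            "hypertension": hypertension[idx],
            "smoking_current": smoking[idx],
            "med_antithrombotic": antithrombotic[idx],
            "change_label": np.where(unfav, "UNFAVORABLE", "FAVORABLE"),
            "evaluable": True,
        }
    )
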