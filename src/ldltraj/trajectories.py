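"""Follow-up linkage, state sequences, truncation, and empirical transition
probabilities.

A repeat measurement is *related* to the previous retained one when the
interval falls in the short-term (2-6 months; default 61-183 days) or
long-term (6-18 months; 184-548 days) evaluation window; anything sooner or
later is an unrelated follow-up and is discarded from trajectory analyses.
Linkage is greedy and forward: the chain re-anchors on the last retained
measurement, so a run of unrelated measurements can still be followed by a
related one.  Patients left with fewer than two retained measurements
contribute no sequence.

Transition probabilities are pooled over all consecutive pairs at every
sequence position (a time-homogeneous estimate).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ehr_model import CohortConfig
from .target_attainment import N_STATES, STATE_LABELS, ldl_states

logger = logging.getLogger(__name__)

__all__ = [
    "FollowUpType",
    "LinkageResult",
    "TransitionMatrix",
    "classify_follow_up",
    "link_measurements",
    "truncate_sequences",
    "transition_matrix",
    "state_distributions",
    "sequence_arrays",
]


class FollowUpType(str, enum.Enum):
    SHORT = "SHORT"
    LONG = "LONG"
    UNRELATED = "UNRELATED"


def classify_follow_up(delta_days: int, config: CohortConfig | None = None) -> FollowUpType:
    """Classify an inter-measurement interval in days.

    SHORT iff short_min <= delta <= short_max; LONG iff
    short_max < delta <= long_max; otherwise UNRELATED.  An interval
    exactly at the short/long boundary is SHORT (the guideline windows
    overlap at 6 months; the lower window wins).
    """
    config = config or CohortConfig()
    if delta_days <= 0:
        raise ValueError("measurements must be strictly ordered (delta_days >= 1)")
    if config.short_min_days <= delta_days <= config.short_max_days:
        return FollowUpType.SHORT
    if config.short_max_days < delta_days <= config.long_max_days:
        return FollowUpType.LONG
    return FollowUpType.UNRELATED


@dataclass
class LinkageResult:
    """Sequences in long format plus discard bookkeeping.

    sequences columns: patient_id, seq_index (1-based), date, ldl, state,
    follow_up_type (None for the first element).
    """

    sequences: pd.DataFrame
    n_input_measurements: int
    n_discarded_unrelated: int
    n_singleton_input: int  # patients entering with a single measurement
    n_reduced_to_single: int  # patients reduced to one retained measurement

    @property
    def n_in_sequences(self) -> int:
        return len(self.sequences)

    def conserves(self) -> bool:
        dropped_singletons = self.n_singleton_input + self.n_reduced_to_single
        return (
            self.n_input_measurements
            == self.n_in_sequences + self.n_discarded_unrelated + dropped_singletons
        )


_SEQ_COLUMNS = ["patient_id", "seq_index", "date", "ldl", "state", "follow_up_type"]


def link_measurements(
    contexts: pd.DataFrame, config: CohortConfig | None = None
) -> LinkageResult:
    """Greedy forward chaining of each patient's dated measurements.

    The first measurement anchors the chain; each subsequent measurement is
    retained iff its interval from the last retained measurement is SHORT
    or LONG, else discarded as unrelated.
    """
    config = config or CohortConfig()
    ctx = contexts.sort_values(["patient_id", "date"], kind="mergesort")
    states = ldl_states(ctx["ldl"].to_numpy(), config.ldl_target)
    ctx = ctx.assign(state=states)

    rows = []
    n_unrelated = 0
    n_singleton_input = 0
    n_reduced = 0
    for pid, grp in ctx.groupby("patient_id", sort=True):
        dates = grp["date"].to_numpy()
        if len(dates) == 1:
            n_singleton_input += 1
            continue
        ldl = grp["ldl"].to_numpy()
        st = grp["state"].to_numpy()
        kept = [(dates[0], ldl[0], st[0], None)]
        anchor = dates[0]
        for j in range(1, len(dates)):
            delta = int((dates[j] - anchor) / np.timedelta64(1, "D"))
            ftype = classify_follow_up(delta, config)
            if ftype is FollowUpType.UNRELATED:
                n_unrelated += 1
            else:
                kept.append((dates[j], ldl[j], st[j], ftype.value))
                anchor = dates[j]
        if len(kept) < 2:
            n_reduced += 1
            continue
        for i, (d, l, s, f) in enumerate(kept, start=1):
            rows.append((pid, i, d, l, s, f))
    sequences = pd.DataFrame(rows, columns=_SEQ_COLUMNS)
    # patients reduced to exactly one retained measurement contribute that
    # one measurement to the dropped-singleton bucket
    result = LinkageResult(
        sequences=sequences,
        n_input_measurements=len(ctx),
        n_discarded_unrelated=n_unrelated,
        n_singleton_input=n_singleton_input,
        n_reduced_to_single=n_reduced,
    )
    logger.info(
        "link_measurements: %d measurements -> %d sequence elements "
        "(%d unrelated discarded, %d single-measurement patients, %d reduced to one)",
        result.n_input_measurements, result.n_in_sequences,
        n_unrelated, n_singleton_input, n_reduced,
    )
    return result


def truncate_sequences(
    sequences: pd.DataFrame, percentile: float = 75.0
) -> tuple[pd.DataFrame, int]:
    """Truncate every sequence to the nearest-rank percentile of lengths.

    The cutoff k is the ceil(p/100 * n)-th smallest sequence length; each
    sequence keeps its first min(length, k) elements.  Returns (truncated
    sequences, k).
    """
    if sequences.empty:
        raise ValueError("no sequences to truncate")
    lengths = np.sort(sequences.groupby("patient_id")["seq_index"].max().to_numpy())
    rank = int(np.ceil(percentile / 100.0 * len(lengths)))
    k = int(lengths[max(rank, 1) - 1])
    out = sequences[sequences["seq_index"] <= k].reset_index(drop=True)
    return out, k


@dataclass
class TransitionMatrix:
    """Pooled pairwise transition counts and row-normalized probabilities."""

    counts: np.ndarray  # (6, 6) int
    probs: np.ndarray  # (6, 6) float; rows with zero total stay 0
    row_totals: np.ndarray  # (6,) int

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        idx = pd.Index(STATE_LABELS, name="from_state")
        return (
            pd.DataFrame(self.counts, index=idx, columns=STATE_LABELS),
            pd.DataFrame(self.probs, index=idx, columns=STATE_LABELS),
        )


def transition_matrix(sequences: pd.DataFrame) -> TransitionMatrix:
    """Empirical 6x6 transition matrix pooled over ALL consecutive pairs of
    every sequence (the first element of a pair may sit at any position)."""
    seq = sequences.sort_values(["patient_id", "seq_index"], kind="mergesort")
    states = seq["state"].to_numpy(dtype=int)
    same_patient = seq["patient_id"].to_numpy()[1:] == seq["patient_id"].to_numpy()[:-1]
    consecutive = seq["seq_index"].to_numpy()[1:] == seq["seq_index"].to_numpy()[:-1] + 1
    pair_mask = same_patient & consecutive
    frm = states[:-1][pair_mask]
    to = states[1:][pair_mask]
    counts = np.zeros((N_STATES, N_STATES), dtype=int)
    np.add.at(counts, (frm, to), 1)
    row_totals = counts.sum(axis=1)
    probs = np.divide(
        counts, row_totals[:, None], out=np.zeros_like(counts, dtype=float),
        where=row_totals[:, None] > 0,
    )
    return TransitionMatrix(counts=counts, probs=probs, row_totals=row_totals)


def state_distributions(sequences: pd.DataFrame) -> pd.DataFrame:
    """Distribution over the 6 states at each sequence position.

    Row i (position i, 1-based) is computed among sequences of length >= i
    and sums to 1; a ``denominator`` column carries that count.
    """
    if sequences.empty:
        return pd.DataFrame(columns=["seq_index"] + STATE_LABELS + ["denominator"])
    tab = (
        sequences.groupby(["seq_index", "state"]).size().unstack(fill_value=0)
        .reindex(columns=range(N_STATES), fill_value=0)
    )
    denom = tab.sum(axis=1)
    dist = tab.div(denom, axis=0)
    dist.columns = STATE_LABELS
    dist["denominator"] = denom.astype(int)
    return dist.reset_index()


def sequence_arrays(sequences: pd.DataFrame) -> tuple[list[str], list[np.ndarray]]:
    """Per-patient integer state arrays (ordered by patient_id) — the input
    shape expected by the optimal-matching stage."""
    ids, arrays = [], []
    for pid, grp in sequences.sort_values(["patient_id", "seq_index"], kind="mergesort").groupby(
        "patient_id", sort=True
    ):
        ids.append(pid)
        arrays.append(grp["state"].to_numpy(dtype=int))
    return ids, arrays
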