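"""Follow-up linkage, truncation and transition estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldltraj.ehr_model import CohortConfig
from ldltraj.preprocess import build_contexts
from ldltraj.synthetic_data import (
    default_transition_matrix,
    sequences_frame,
    simulate_state_sequences,
    stationary_distribution,
)
from ldltraj.trajectories import (
    FollowUpType,
    classify_follow_up,
    link_measurements,
    state_distributions,
    transition_matrix,
    truncate_sequences,
)


@pytest.mark.parametrize(
    "delta,expected",
    [
        (90, FollowUpType.SHORT),
        (61, FollowUpType.SHORT),
        (183, FollowUpType.SHORT),   # boundary: lower window wins
        (184, FollowUpType.LONG),
        (365, FollowUpType.LONG),
        (548, FollowUpType.LONG),
        (30, FollowUpType.UNRELATED),
        (60, FollowUpType.UNRELATED),
        (549, FollowUpType.UNRELATED),
        (600, FollowUpType.UNRELATED),
    ],
)
def test_classify_follow_up(delta, expected, config):
    assert classify_follow_up(delta, config) == expected


def test_nonpositive_delta_rejected(config):
    with pytest.raises(ValueError):
        classify_follow_up(0, config)


@given(delta=st.integers(min_value=1, max_value=1000))
@settings(deadline=None, max_examples=200)
def test_follow_up_partitions_positive_days(delta):
    """Every positive interval maps to exactly one follow-up type."""
    ftype = classify_follow_up(delta)
    cfg = CohortConfig()
    in_short = cfg.short_min_days <= delta <= cfg.short_max_days
    in_long = cfg.short_max_days < delta <= cfg.long_max_days
    assert [in_short, in_long, not (in_short or in_long)].count(True) >= 1
    assert ftype == (
        FollowUpType.SHORT if in_short
        else FollowUpType.LONG if in_long
        else FollowUpType.UNRELATED
    )


def _ctx_from_intervals(intervals, start="2010-01-01"):
    dates = [pd.Timestamp(start)]
    for d in intervals:
        dates.append(dates[-1] + pd.Timedelta(days=d))
    return pd.DataFrame(
        {"patient_id": "A", "date": dates, "ldl": 2.0, "ldl_source": "measured"}
    )


def test_link_all_related(config):
    res = link_measurements(_ctx_from_intervals([90, 90]), config)
    assert len(res.sequences) == 3
    assert list(res.sequences["follow_up_type"]) == [None, "SHORT", "SHORT"]


def test_link_greedy_reanchors_on_last_retained(config):
    """Intervals [30, 60]: second measurement unrelated (30 d), third kept
    because its interval from the FIRST retained is 90 d."""
    res = link_measurements(_ctx_from_intervals([30, 60]), config)
    assert len(res.sequences) == 2
    assert res.n_discarded_unrelated == 1
    kept_dates = list(res.sequences["date"])
    assert kept_dates == [pd.Timestamp("2010-01-01"), pd.Timestamp("2010-04-01")]


def test_single_measurement_patient_contributes_nothing(config):
    res = link_measurements(_ctx_from_intervals([]), config)
    assert res.sequences.empty and res.n_singleton_input == 1
    assert res.conserves()


def test_reduced_to_single_counted(config):
    res = link_measurements(_ctx_from_intervals([30]), config)
    assert res.sequences.empty
    assert res.n_discarded_unrelated == 1 and res.n_reduced_to_single == 1
    assert res.conserves()


def test_linkage_conservation_on_cohort(small_cohort, config):
    tables, _ = small_cohort
    ctx, _ = build_contexts(tables, config)
    res = link_measurements(ctx, config)
    assert res.conserves()
    lengths = res.sequences.groupby("patient_id")["seq_index"].max()
    assert (lengths >= 2).all()


def _seqs_of_lengths(lengths):
    arrays = [np.zeros(l, dtype=int) for l in lengths]
    return sequences_frame(arrays)


def test_truncation_nearest_rank():
    """Lengths [2,2,3,6,8] at p=75: k = ceil(0.75*5) = 4th smallest = 6."""
    seqs = _seqs_of_lengths([2, 2, 3, 6, 8])
    truncated, k = truncate_sequences(seqs, 75)
    assert k == 6
    assert truncated.groupby("patient_id")["seq_index"].max().max() == 6


def test_truncation_p100_no_op():
    seqs = _seqs_of_lengths([2, 5, 9])
    truncated, k = truncate_sequences(seqs, 100)
    assert k == 9 and len(truncated) == len(seqs)


def test_truncation_equal_lengths_unchanged():
    seqs = _seqs_of_lengths([4, 4, 4])
    truncated, k = truncate_sequences(seqs, 75)
    assert k == 4 and len(truncated) == len(seqs)


def test_transition_matrix_small_cases():
    tm = transition_matrix(sequences_frame([np.array([0, 0, 0])]))
    assert tm.probs[0, 0] == 1.0 and tm.row_totals[0] == 2
    tm = transition_matrix(sequences_frame([np.array([0, 1]), np.array([0, 0])]))
    assert tm.probs[0, 0] == 0.5 and tm.probs[0, 1] == 0.5


def test_transition_rows_stochastic(small_cohort, config):
    tables, _ = small_cohort
    ctx, _ = build_contexts(tables, config)
    res = link_measurements(ctx, config)
    tm = transition_matrix(res.sequences)
    populated = tm.row_totals > 0
    np.testing.assert_allclose(tm.probs[populated].sum(axis=1), 1.0, atol=1e-9)
    assert tm.counts.sum() == len(res.sequences) - res.sequences["patient_id"].nunique()


def test_transition_recovery_within_3se():
    """Entries estimated from simulated chains lie within 3 binomial SEs."""
    P = default_transition_matrix()
    rng = np.random.default_rng(123)
    lengths = rng.integers(2, 7, size=4000)
    seqs = simulate_state_sequences(P, lengths, rng)
    tm = transition_matrix(sequences_frame(seqs))
    for i in range(6):
        n = tm.row_totals[i]
        se = np.sqrt(P[i] * (1 - P[i]) / n)
        assert np.all(np.abs(tm.probs[i] - P[i]) <= 3 * np.maximum(se, 1e-12) + 1e-12)


def test_state_distribution_definitions():
    seqs = sequences_frame([np.array([0, 2]), np.array([0, 1, 1])])
    dist = state_distributions(seqs)
    assert dist.loc[dist["seq_index"] == 1, "ON_TARGET"].iloc[0] == 1.0
    assert dist.loc[dist["seq_index"] == 3, "denominator"].iloc[0] == 1
    state_cols = [c for c in dist.columns if c not in ("seq_index", "denominator")]
    np.testing.assert_allclose(dist[state_cols].sum(axis=1), 1.0, atol=1e-12)


def test_stationary_chain_distributions_flat_across_indices():
    """With stationary initialization, each index's state distribution is
    consistent with the stationary distribution (chi-square GoF)."""
    from scipy.stats import chisquare

    P = default_transition_matrix()
    pi = stationary_distribution(P)
    rng = np.random.default_rng(42)
    seqs = simulate_state_sequences(P, np.full(4000, 4), rng, initial=pi)
    dist = state_distributions(sequences_frame(seqs))
    state_cols = dist.columns[1:7]
    for _, row in dist.iterrows():
        n = row["denominator"]
        observed = row[state_cols].to_numpy(float) * n
        _, p = chisquare(observed, pi * n)
        assert p > 1e-5
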