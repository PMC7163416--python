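"""Optimal matching distances, clustering, and cluster models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ldltraj.sequence_clustering import (
    SubstitutionCosts,
    cluster_covariate_model,
    cluster_sequences,
    om_distance,
    pairwise_distances,
    substitution_costs,
)
from ldltraj.trajectories import TransitionMatrix

from _oracles import om_oracle


CONST = substitution_costs("constant", constant_value=2.0, indel=1.0)


def test_constant_costs_shape():
    m = CONST.matrix
    assert np.all(np.diag(m) == 0)
    off = m[~np.eye(6, dtype=bool)]
    assert np.all(off == 2.0)


def test_trate_costs_formula():
    probs = np.full((6, 6), 1 / 6)
    probs[0, 1], probs[1, 0] = 0.10, 0.30
    probs[0, 0] = 1 - probs[0, 1:].sum()
    probs[1, 1] = 1 - probs[1, [0, 2, 3, 4, 5]].sum()
    tm = TransitionMatrix(
        counts=(probs * 600).astype(int), probs=probs, row_totals=np.full(6, 600)
    )
    costs = substitution_costs("trate", transition=tm)
    assert costs.matrix[0, 1] == pytest.approx(2 - 0.10 - 0.30)
    assert costs.matrix[0, 1] == costs.matrix[1, 0]
    assert np.all(np.diag(costs.matrix) == 0)


def test_trate_empty_row_raises():
    tm = TransitionMatrix(
        counts=np.zeros((6, 6), int), probs=np.zeros((6, 6)), row_totals=np.zeros(6, int)
    )
    with pytest.raises(ValueError, match="ON_TARGET"):
        substitution_costs("trate", transition=tm)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        ([0, 1, 2], [0, 1, 2], 0.0),          # identical
        ([0], [0, 1], 1.0),                   # one insertion
        ([0, 1], [0, 0], 2.0),                # substitution vs delete+insert tie
        ([], [1, 2], 2.0),                    # all indels
        ([3], [4], 2.0),                      # single substitution
    ],
)
def test_om_distance_examples(a, b, expected):
    assert om_distance(np.array(a, int), np.array(b, int), CONST) == pytest.approx(expected)


def test_om_unknown_symbol_rejected():
    with pytest.raises(ValueError):
        om_distance(np.array([9]), np.array([0]), CONST)


def test_om_matches_oracle_random_sample():
    """DP equals the exhaustive alignment oracle on random short pairs."""
    rng = np.random.default_rng(5)
    for _ in range(60):
        a = rng.integers(0, 6, rng.integers(1, 5))
        b = rng.integers(0, 6, rng.integers(1, 5))
        assert om_distance(a, b, CONST) == pytest.approx(om_oracle(a, b, CONST))


def test_om_matches_oracle_uneven_costs():
    rng = np.random.default_rng(6)
    m = rng.uniform(0.5, 3.0, (6, 6))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    costs = SubstitutionCosts(matrix=m, indel=0.9)
    for _ in range(40):
        a = rng.integers(0, 6, rng.integers(1, 5))
        b = rng.integers(0, 6, rng.integers(1, 5))
        assert om_distance(a, b, costs) == pytest.approx(om_oracle(a, b, costs))


@given(data=st.data())
@settings(deadline=None, max_examples=60)
def test_om_metric_properties(data):
    """Symmetry, indel upper bound, and triangle inequality (constant costs)."""
    seq = st.lists(st.integers(0, 5), min_size=1, max_size=6)
    a = np.array(data.draw(seq), int)
    b = np.array(data.draw(seq), int)
    c = np.array(data.draw(seq), int)
    dab = om_distance(a, b, CONST)
    assert dab == pytest.approx(om_distance(b, a, CONST))
    assert dab <= CONST.indel * (len(a) + len(b)) + 1e-12
    assert dab <= om_distance(a, c, CONST) + om_distance(c, b, CONST) + 1e-9


def test_equal_length_constant_cost_bounded_by_hamming():
    """For equal lengths, the identity alignment costs c * Hamming, so the
    OM distance never exceeds it (indel shifts can undercut it, e.g.
    [0,1,2,3] vs [1,2,3,4] costs 2 by delete+insert, not 8)."""
    rng = np.random.default_rng(8)
    for _ in range(30):
        n = rng.integers(1, 7)
        a, b = rng.integers(0, 6, n), rng.integers(0, 6, n)
        assert om_distance(a, b, CONST) <= 2.0 * (a != b).sum() + 1e-12
    assert om_distance(np.arange(4), np.arange(1, 5), CONST) == pytest.approx(2.0)
    # without a shift advantage the bound is attained
    assert om_distance(np.array([0, 1]), np.array([0, 2]), CONST) == pytest.approx(2.0)


def test_pairwise_distance_matrix_properties():
    rng = np.random.default_rng(9)
    seqs = [rng.integers(0, 6, rng.integers(2, 6)) for _ in range(12)]
    D = pairwise_distances(seqs, CONST)
    assert np.allclose(D, D.T) and np.all(np.diag(D) == 0) and np.all(D >= 0)
    # permutation consistency
    perm = rng.permutation(12)
    D2 = pairwise_distances([seqs[i] for i in perm], CONST)
    assert np.allclose(D2, D[np.ix_(perm, perm)])


def test_identical_sequences_zero_matrix():
    seqs = [np.array([1, 2, 3]), np.array([1, 2, 3])]
    assert np.all(pairwise_distances(seqs, CONST) == 0)


def test_clustering_separates_constructed_bundles():
    """All-on-target vs all-worst-state sequences split perfectly at k=2."""
    good = [np.zeros(4, int) for _ in range(10)]
    bad = [np.full(4, 5, int) for _ in range(8)]
    D = pairwise_distances(good + bad, CONST)
    labels, summary = cluster_sequences(D, 2)
    assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
    assert labels[0] != labels[10]
    # labels numbered by size: the bigger (good) bundle is cluster 1
    assert labels[0] == 1
    assert list(summary["n"]) == [10, 8]


def test_k_equals_n_minus_1_merges_one_pair():
    rng = np.random.default_rng(10)
    seqs = [rng.integers(0, 6, 4) for _ in range(6)]
    D = pairwise_distances(seqs, CONST)
    labels, _ = cluster_sequences(D, 5)
    sizes = sorted(np.bincount(labels)[1:], reverse=True)
    assert sizes == [2, 1, 1, 1, 1]


def test_duplicates_cocluster():
    seqs = [np.array([0, 0]), np.array([0, 0]), np.array([5, 5]), np.array([3, 1])]
    D = pairwise_distances(seqs, CONST)
    labels, _ = cluster_sequences(D, 3)
    assert labels[0] == labels[1]


def test_n_clusters_out_of_range():
    D = pairwise_distances([np.array([0]), np.array([1]), np.array([2])], CONST)
    with pytest.raises(ValueError):
        cluster_sequences(D, 3)


def test_cluster_covariate_model_contingency_oracle():
    """Binary covariate, one-vs-rest: OR equals the 2x2 cross-product."""
    rng = np.random.default_rng(11)
    labels = np.array([1] * 60 + [2] * 60)
    x = np.concatenate([rng.random(60) < 0.7, rng.random(60) < 0.3]).astype(float)
    cov = pd.DataFrame({"x": x})
    models = cluster_covariate_model(labels, cov, ["x"])
    member = labels == 1
    a = ((x == 1) & member).sum(); b = ((x == 0) & member).sum()
    c = ((x == 1) & ~member).sum(); d = ((x == 0) & ~member).sum()
    assert models[1].loc["x", "or_"] == pytest.approx(a * d / (b * c), rel=1e-6)


def test_small_cluster_skipped():
    labels = np.array([1] * 50 + [2] * 5)
    cov = pd.DataFrame({"x": np.random.default_rng(1).random(55)})
    models = cluster_covariate_model(labels, cov, ["x"], min_cluster_size=10)
    assert 2 not in models
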