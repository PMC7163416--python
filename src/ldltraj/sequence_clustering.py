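"""Optimal-matching dissimilarity between state sequences, hierarchical
clustering, and cluster-membership covariate models.

Optimal matching is the classical sequence-analysis edit distance: the
minimum total cost of turning one categorical sequence into another using
substitutions (priced by a symmetric 6x6 cost matrix) and insertions/
deletions (a single indel cost), solved by dynamic programming on the
(|a|+1) x (|b|+1) grid.  Defaults are the conventional constant
substitution cost 2 with indel cost 1; transition-rate-derived costs
cost(i,j) = 2 - P(i->j) - P(j->i) are available as the ``trate`` method.

Clustering is agglomerative with the Ward-type update applied to the
squared dissimilarities (the standard Lance-Williams rule); the input
dissimilarity is not Euclidean, so Ward here is heuristic — which is the
common practice for optimal-matching distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .target_attainment import N_STATES, STATE_LABELS, fit_logistic_or
from .trajectories import TransitionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SubstitutionCosts",
    "substitution_costs",
    "om_distance",
    "pairwise_distances",
    "cluster_sequences",
    "silhouette_by_k",
    "cluster_covariate_model",
]


@dataclass
class SubstitutionCosts:
    matrix: np.ndarray  # (6, 6) symmetric, zero diagonal
    indel: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_STATES, N_STATES):
            raise ValueError(f"substitution matrix must be {N_STATES}x{N_STATES}")
        if not np.allclose(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("substitution matrix must have zero diagonal")
        if np.any(m < 0) or self.indel <= 0:
            raise ValueError("costs must be non-negative, indel positive")
        self.matrix = m
        if m.max() > 2 * self.indel:
            # substitutions above 2*indel are never used by the DP
            logger.info(
                "max substitution cost %.3g exceeds 2*indel=%.3g", m.max(), 2 * self.indel
            )


def substitution_costs(
    method: str = "constant",
    transition: TransitionMatrix | None = None,
    constant_value: float = 2.0,
    indel: float = 1.0,
) -> SubstitutionCosts:
    """Build the substitution-cost matrix.

    ``constant``: all off-diagonal costs equal ``constant_value``.
    ``trate``: cost(i,j) = 2 - P(i->j) - P(j->i) from an estimated
    transition matrix, clipped at zero; requires every row populated.
    """
    if method == "constant":
        m = np.full((N_STATES, N_STATES), float(constant_value))
        np.fill_diagonal(m, 0.0)
        return SubstitutionCosts(matrix=m, indel=indel)
    if method == "trate":
        if transition is None:
            raise ValueError("trate costs require a TransitionMatrix")
        empty = np.flatnonzero(transition.row_totals == 0)
        if len(empty):
            raise ValueError(
                f"trate costs undefined: empty transition row for state "
                f"{STATE_LABELS[empty[0]]}"
            )
        p = transition.probs
        m = np.clip(2.0 - p - p.T, 0.0, None)
        np.fill_diagonal(m, 0.0)
        return SubstitutionCosts(matrix=m, indel=indel)
    raise ValueError(f"unknown substitution method {method!r}")


def om_distance(seq_a: np.ndarray, seq_b: np.ndarray, costs: SubstitutionCosts) -> float:
    """Optimal-matching distance between two integer state sequences."""
    a = np.asarray(seq_a, dtype=int)
    b = np.asarray(seq_b, dtype=int)
    for s in (a, b):
        if len(s) and (s.min() < 0 or s.max() >= N_STATES):
            raise ValueError("unknown state symbol in sequence")
    ind = costs.indel
    sub = costs.matrix
    la, lb = len(a), len(b)
    prev = np.arange(lb + 1, dtype=float) * ind
    for i in range(1, la + 1):
        cur = np.empty(lb + 1)
        cur[0] = i * ind
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cur[j] = min(
                prev[j - 1] + sub[ai, b[j - 1]],  # substitute / match
                prev[j] + ind,  # delete from a
                cur[j - 1] + ind,  # insert into a
            )
        prev = cur
    return float(prev[lb])


def pairwise_distances(
    sequences: list[np.ndarray], costs: SubstitutionCosts
) -> np.ndarray:
    """Symmetric matrix of optimal-matching distances.

    Identical sequences are computed once (the distance depends only on
    sequence content).
    """
    n = len(sequences)
    if n < 2:
        raise ValueError("need at least two sequences")
    keys = [tuple(np.asarray(s, dtype=int)) for s in sequences]
    unique = sorted(set(keys))
    uindex = {k: i for i, k in enumerate(unique)}
    uarrs = [np.array(k, dtype=int) for k in unique]
    m = len(unique)
    ud = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            ud[i, j] = ud[j, i] = om_distance(uarrs[i], uarrs[j], costs)
    idx = np.array([uindex[k] for k in keys])
    return ud[np.ix_(idx, idx)]


def cluster_sequences(
    distances: np.ndarray, n_clusters: int
) -> tuple[np.ndarray, pd.DataFrame]:
    """Ward-type agglomerative clustering on a precomputed dissimilarity.

    Returns 1-based labels numbered by cluster size (descending; ties by
    first occurrence) and a per-cluster summary with the mean share of
    off-target states and the mean worst (maximum) state per sequence —
    computed later by the caller if sequences are supplied; here the
    summary carries sizes only.
    """
    n = distances.shape[0]
    if not (2 <= n_clusters <= n - 1):
        raise ValueError(f"n_clusters must be in [2, {n - 1}]")
    condensed = squareform(distances, checks=False)
    Z = linkage(condensed, method="ward")
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    # renumber deterministically: by size descending, ties by first index
    order = sorted(
        np.unique(raw),
        key=lambda c: (-(raw == c).sum(), int(np.flatnonzero(raw == c)[0])),
    )
    relabel = {c: i + 1 for i, c in enumerate(order)}
    labels = np.array([relabel[c] for c in raw])
    sizes = pd.Series(labels).value_counts().sort_index()
    summary = pd.DataFrame({"cluster": sizes.index, "n": sizes.to_numpy()})
    return labels, summary


def cluster_profiles(labels: np.ndarray, sequences: list[np.ndarray]) -> pd.DataFrame:
    """Per-cluster trajectory profile: mean off-target share and mean worst
    state over member sequences."""
    rows = []
    for c in np.unique(labels):
        member = [s for s, l in zip(sequences, labels) if l == c]
        off_share = float(np.mean([np.mean(np.asarray(s) != 0) for s in member]))
        worst = float(np.mean([np.max(s) for s in member]))
        rows.append({"cluster": int(c), "n": len(member),
                     "mean_off_target_share": off_share, "mean_worst_state": worst})
    return pd.DataFrame(rows)


def silhouette_by_k(
    distances: np.ndarray, k_values=range(2, 9)
) -> pd.DataFrame:
    """Mean silhouette width per candidate cluster count (precomputed
    metric), to aid choosing k."""
    rows = []
    for k in k_values:
        if k > distances.shape[0] - 1:
            break
        labels, _ = cluster_sequences(distances, k)
        rows.append(
            {"k": k, "silhouette": float(silhouette_score(distances, labels, metric="precomputed"))}
        )
    return pd.DataFrame(rows)


def cluster_covariate_model(
    labels: np.ndarray,
    covariates: pd.DataFrame,
    covariate_names: list[str],
    min_cluster_size: int = 10,
) -> dict[int, pd.DataFrame]:
    """One-vs-rest binomial logistic model per cluster.

    ``covariates`` has one row per sequence, aligned with ``labels``.
    Clusters smaller than ``min_cluster_size`` are skipped with a warning.
    Returns {cluster: odds-ratio table}.
    """
    if len(labels) != len(covariates):
        raise ValueError("labels and covariates must align")
    out = {}
    df = covariates.copy().reset_index(drop=True)
    for c in sorted(np.unique(labels)):
        size = int((labels == c).sum())
        if size < min_cluster_size:
            logger.warning("cluster %d has %d members (<%d): model skipped",
                           c, size, min_cluster_size)
            continue
        df["_member"] = (labels == c).astype(int)
        try:
            out[int(c)] = fit_logistic_or(df, "_member", covariate_names)
        finally:
            df.drop(columns="_member", inplace=True)
    return out
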