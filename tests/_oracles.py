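"""Independent brute-force oracles used by the test suite."""

import itertools

from ldltraj.sequence_clustering import SubstitutionCosts


def om_oracle(a, b, costs: SubstitutionCosts) -> float:
    """Exhaustive alignment enumeration (independent of the DP).

    Enumerates every order-preserving matching between positions of a and
    b; matched pairs cost min(substitution, 2*indel), unmatched positions
    cost one indel each.  Exact for all cost settings, feasible for short
    sequences.
    """
    ind = costs.indel
    sub = costs.matrix
    best = ind * (len(a) + len(b))
    for k in range(1, min(len(a), len(b)) + 1):
        for ia in itertools.combinations(range(len(a)), k):
            for ib in itertools.combinations(range(len(b)), k):
                cost = sum(
                    min(sub[a[i], b[j]], 2 * ind) for i, j in zip(ia, ib)
                ) + ind * (len(a) + len(b) - 2 * k)
                best = min(best, cost)
    return best
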