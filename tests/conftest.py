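import itertools
import math

import numpy as np
import pytest

from pathpool.pathway_model import (InteractionEdge, PathwayGraph,
                                    build_pooled)

# ---------------------------------------------------------------------------
# independent oracles (pure enumeration / closed form, no package internals)


def hypergeom_tail_oracle(k: int, K: int, n: int, M: int) -> float:
    """P(X >= k) for X ~ hypergeometric(M, K, n) by direct enumeration."""
    total = math.comb(M, n)
    return sum(math.comb(K, x) * math.comb(M - K, n - x)
               for x in range(k, min(K, n) + 1)) / total


def fisher_two_oracle(p1: float, p2: float) -> float:
    """Closed form of Fisher's method for two p-values: q(1 - ln q)."""
    q = p1 * p2
    return q * (1.0 - math.log(q))


def exact_permutation_pvalues(adjacency: np.ndarray, weights: np.ndarray,
                              floor: float | None = None) -> np.ndarray:
    """Exact permutation null for neighbour-sum scores by full enumeration.

    For every gene i, the fraction of the n! permutations of the weight
    vector whose score A_i. @ w_perm strictly exceeds the observed score.
    """
    A = adjacency.astype(float)
    si = A @ weights
    n = len(weights)
    count = np.zeros(n)
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        count += (A @ weights[list(perm)]) > si
    p = count / total
    if floor is not None:
        p = np.maximum(p, floor)
    return p


def exact_pair_pvalue(adjacency: np.ndarray, weights: np.ndarray,
                      ia: np.ndarray, ib: np.ndarray) -> float:
    """Exact permutation p-value for a cross-pathway score by enumeration."""
    B = adjacency[np.ix_(ia, ib)].astype(float)
    sc = weights[ia] @ B @ weights[ib]
    count = total = 0
    for perm in itertools.permutations(range(len(weights))):
        w = weights[list(perm)]
        total += 1
        count += (w[ia] @ B @ w[ib]) > sc
    return count / total


# ---------------------------------------------------------------------------
# shared fixtures


@pytest.fixture
def chain_pooled():
    """a -> b -> c with one undirected binding edge {c, d}."""
    pw1 = PathwayGraph("P1", edges=[InteractionEdge("a", "b", "activation"),
                                    InteractionEdge("b", "c", "inhibition")])
    pw2 = PathwayGraph("P2", edges=[InteractionEdge("c", "d",
                                                    "binding/association",
                                                    directed=False)])
    return build_pooled([pw1, pw2])


@pytest.fixture
def tiny_rng():
    return np.random.default_rng(12345)
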