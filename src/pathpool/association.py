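"""Contextual pathway-pathway association on the pooled graph.

The contextual score from pathway alpha to pathway beta,

    SC_ab = sum_{i in g^a} sum_{j in g^b} A_ij * (-log10 p_i^D) * (-log10 p_j^D),

sums evidence over adjacency edges running from alpha's genes into beta's
genes, so two pathways can associate through differential expression of
connected genes even when they share no gene at all.  Significance comes
from the same shuffle null as the indirect evidence: all p^D values are
permuted over the pooled genes N times with the topology fixed, and the
p-value counts shuffled scores strictly exceeding the observed one (floored
at 1/N).  A static hypergeometric gene-overlap test is provided for
contrast: it sees only the membership annotation, never the expression data.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from . import evidence as ev
from .enrichment import hypergeom_tail
from .pathway_model import PooledPathway


def _cross_block(pooled: PooledPathway, a: str, b: str):
    ia = pooled.member_indices(a)
    ib = pooled.member_indices(b)
    return ia, ib, pooled.adjacency[np.ix_(ia, ib)]


def contextual_score(pooled: PooledPathway, p_direct: dict[str, float],
                     a: str, b: str) -> float:
    """Directional score SC_ab; SC_ab != SC_ba in general."""
    w = ev._weights(pooled, p_direct)
    ia, ib, block = _cross_block(pooled, a, b)
    if block.size == 0:
        return 0.0
    return float(w[ia] @ block.astype(float) @ w[ib])


def cross_edge_count(pooled: PooledPathway, a: str, b: str) -> int:
    """Number of adjacency edges from genes of a into genes of b."""
    return int(_cross_block(pooled, a, b)[2].sum())


def association_pvalues(pooled: PooledPathway, p_direct: dict[str, float],
                        null: ev.NullConfig,
                        pairs: list[tuple[str, str]],
                        *, ties: str = "gt") -> dict[tuple[str, str], float]:
    """Permutation p-values p_ab for ordered pathway pairs.

    One shared set of N full-weight-vector shuffles is drawn per call and
    reused across every pair, so (a, b) and (b, a) are scored against the
    same null draws.
    """
    w = ev._weights(pooled, p_direct)
    N = null.n_shuffles
    rng = np.random.default_rng(null.seed)
    W = ev.permutation_weight_matrix(w, N, rng)
    out: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        ia, ib, block = _cross_block(pooled, a, b)
        if block.size == 0 or not block.any():
            sc = 0.0
            sc_rand = np.zeros(N)
        else:
            B = block.astype(float)
            sc = float(w[ia] @ B @ w[ib])
            sc_rand = np.einsum("in,in->n", W[ia], B @ W[ib])
        if ties == "gt":
            count = int((sc_rand > sc).sum())
            out[(a, b)] = max(count / N, 1.0 / N)
        elif ties == "ge":
            count = int((sc_rand >= sc).sum())
            out[(a, b)] = (count + 1) / (N + 1)
        else:
            raise ValueError(f"unknown ties convention {ties!r}")
    return out


def static_overlap_test(pooled: PooledPathway, a: str, b: str,
                        universe_size: int) -> float:
    """Hypergeometric p-value for the gene overlap of two pathways.

    Uses the pathway memberships as annotated (call on the pre-restriction
    pooled graph for the full gene complement).
    """
    ga, gb = pooled.membership[a], pooled.membership[b]
    if universe_size < max(len(ga), len(gb)):
        raise ValueError("universe smaller than a pathway")
    return hypergeom_tail(len(ga & gb), len(ga), len(gb), universe_size)


def associate(pooled: PooledPathway, p_direct: dict[str, float],
              null: ev.NullConfig, *,
              pairs: list[tuple[str, str]] | None = None,
              focus: str | None = None,
              overlap_pooled: PooledPathway | None = None,
              overlap_universe: int | None = None,
              symmetrize: str | None = None) -> pd.DataFrame:
    """Association table over ordered pathway pairs.

    By default all ordered pairs are scored; ``focus`` restricts to pairs
    involving one pathway (both directions).  ``overlap_pooled`` supplies
    pre-restriction memberships for the static overlap columns (defaults to
    ``pooled`` itself).  ``symmetrize`` in {None, "max", "sum"} optionally
    aggregates the two directions of each unordered pair.
    """
    pids = list(pooled.membership)
    if pairs is None:
        if focus is not None:
            if focus not in pooled.membership:
                raise KeyError(f"unknown pathway {focus!r}")
            pairs = [(focus, p) for p in pids if p != focus]
            pairs += [(p, focus) for p in pids if p != focus]
        else:
            pairs = [(a, b) for a, b in itertools.permutations(pids, 2)]
    pv = association_pvalues(pooled, p_direct, null, pairs)
    op = overlap_pooled if overlap_pooled is not None else pooled
    uni = overlap_universe if overlap_universe is not None else op.n_genes
    rows = []
    for a, b in pairs:
        ga, gb = op.membership[a], op.membership[b]
        rows.append({
            "pathway_a": a,
            "pathway_b": b,
            "sc": contextual_score(pooled, p_direct, a, b),
            "p_context": pv[(a, b)],
            "n_cross_edges": cross_edge_count(pooled, a, b),
            "n_shared_genes": len(ga & gb),
            "p_overlap": static_overlap_test(op, a, b, uni),
        })
    df = pd.DataFrame(rows)
    if symmetrize is not None:
        if symmetrize not in ("max", "sum"):
            raise ValueError(f"unknown symmetrize mode {symmetrize!r}")
        key = df.apply(lambda r: tuple(sorted((r.pathway_a, r.pathway_b))), axis=1)
        agg = {"sc": symmetrize, "p_context": "min", "n_cross_edges": symmetrize,
               "n_shared_genes": "first", "p_overlap": "first"}
        df = (df.assign(_k=key).groupby("_k", sort=False)
                .agg({**agg, "pathway_a": "first", "pathway_b": "first"})
                .reset_index(drop=True))
        df = df[["pathway_a", "pathway_b", "sc", "p_context",
                 "n_cross_edges", "n_shared_genes", "p_overlap"]]
    return df.sort_values(["p_context", "pathway_a", "pathway_b"],
                          kind="mergesort").reset_index(drop=True)
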