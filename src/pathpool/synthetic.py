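"""Seeded generators for pathway collections and two-group expression data.

Emulates the statistical structure the pooled-pathway method assumes:
a collection of directed pathways with partial gene overlap (consecutive
pathways share a fixed number of genes, in a ring by default), and a
genes x samples expression matrix where differential expression is planted
in designated pathways as a standardized mean shift in the condition group.
Everything is reproducible from the seed, so fixtures never need to be
stored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evidence import ExpressionDataset
from .pathway_model import InteractionEdge, PathwayGraph

logger = logging.getLogger(__name__)


@dataclass
class SyntheticSpec:
    """Parameters of the generated study.

    ``effect_size`` is a standardized mean difference d: planted genes are
    shifted by d * noise_sd in the condition group.  ``de_fraction`` is the
    fraction of a planted pathway's genes that receive the shift; a gene
    belonging to several planted pathways is shifted at most once.
    """

    n_pathways: int = 12
    genes_per_pathway: int = 25
    overlap_fraction: float = 0.2
    edge_density: float = 0.08
    bidirectional_fraction: float = 0.2
    n_per_group: int = 10
    effect_size: float = 1.5
    noise_sd: float = 1.0
    planted_pathways: set[str] = field(default_factory=set)
    de_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not (0 < self.edge_density <= 1):
            raise ValueError("edge_density must be in (0, 1]")
        if not (0 <= self.bidirectional_fraction <= 1):
            raise ValueError("bidirectional_fraction must be in [0, 1]")
        if not (0 < self.de_fraction <= 1):
            raise ValueError("de_fraction must be in (0, 1]")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.genes_per_pathway < 1 or self.n_pathways < 1:
            raise ValueError("need at least one gene and one pathway")
        self.n_shared = int(self.overlap_fraction * self.genes_per_pathway)
        if 2 * self.n_shared > self.genes_per_pathway:
            raise ValueError("overlap_fraction too large: a pathway cannot "
                             "share more than half its genes with each "
                             "ring neighbour")

    def pathway_id(self, k: int) -> str:
        return f"P{k + 1:03d}"


def generate_pathways(spec: SyntheticSpec, *, pattern: str = "ring"
                      ) -> list[PathwayGraph]:
    """Pathway collection with exact consecutive-overlap gene sharing.

    ``pattern="ring"``: pathway k shares its last ``n_shared`` genes with
    pathway k+1's first ``n_shared`` (wrapping around when there are at
    least three pathways).  ``pattern="hub"``: every pathway additionally
    contains a common block of ``n_shared`` hub genes, stressing highly
    shared genes.  Directed edges are sampled at ``edge_density`` over
    ordered within-pathway gene pairs; a ``bidirectional_fraction`` of them
    is relabelled as undirected binding edges.
    """
    if pattern not in ("ring", "hub"):
        raise ValueError(f"unknown sharing pattern {pattern!r}")
    rng = np.random.default_rng(spec.seed)
    P, size, s = spec.n_pathways, spec.genes_per_pathway, spec.n_shared
    wrap = pattern == "ring" and P >= 3 and s > 0

    counter = 0

    def fresh(n: int) -> list[str]:
        nonlocal counter
        out = [f"g{counter + i:05d}" for i in range(n)]
        counter += n
        return out

    memberships: list[list[str]] = []
    if pattern == "hub":
        hub = fresh(s)
        for k in range(P):
            memberships.append(hub + fresh(size - s))
    else:
        prev: list[str] = []
        first: list[str] = []
        for k in range(P):
            last = k == P - 1
            if last and wrap:
                nxt = first
            elif last or s == 0:
                nxt = []
            else:
                nxt = fresh(s)
            own = fresh(size - len(prev) - len(nxt))
            genes = prev + own + nxt
            if k == 0 and wrap:
                first = genes[:s]
            memberships.append(genes)
            prev = nxt

    graphs: list[PathwayGraph] = []
    for k, genes in enumerate(memberships):
        n = len(genes)
        mask = rng.random((n, n)) < spec.edge_density
        np.fill_diagonal(mask, False)
        edges: list[InteractionEdge] = []
        for i, j in zip(*np.nonzero(mask)):
            if rng.random() < spec.bidirectional_fraction:
                edges.append(InteractionEdge(genes[i], genes[j],
                                             "binding/association", False))
            else:
                edges.append(InteractionEdge(genes[i], genes[j],
                                             "activation", True))
        graphs.append(PathwayGraph(pathway_id=spec.pathway_id(k),
                                   name=f"synthetic pathway {k + 1}",
                                   genes=set(genes), edges=edges))
    return graphs


def generate_expression(pathways: list[PathwayGraph],
                        spec: SyntheticSpec) -> ExpressionDataset:
    """Two-group expression matrix with planted differential expression.

    Baseline values are i.i.d. normal(0, noise_sd); in each planted pathway
    a de_fraction subset of genes (chosen reproducibly) is shifted by
    effect_size * noise_sd in the condition group.  Genes in several planted
    pathways are shifted at most once.
    """
    rng = np.random.default_rng(spec.seed + 1)
    gene_ids: list[str] = []
    seen: set[str] = set()
    for pw in pathways:
        for g in sorted(pw.genes):
            if g not in seen:
                seen.add(g)
                gene_ids.append(g)
    n = spec.n_per_group
    values = rng.normal(0.0, spec.noise_sd, size=(len(gene_ids), 2 * n))
    groups = np.array(["control"] * n + ["condition"] * n)

    index = {g: i for i, g in enumerate(gene_ids)}
    shifted: set[str] = set()
    for pw in pathways:
        if pw.pathway_id not in spec.planted_pathways:
            continue
        members = sorted(pw.genes)
        n_de = max(1, round(spec.de_fraction * len(members)))
        chosen = rng.choice(len(members), size=n_de, replace=False)
        for c in sorted(chosen):
            g = members[c]
            if g in shifted:
                continue
            shifted.add(g)
            values[index[g], n:] += spec.effect_size * spec.noise_sd
    ds = ExpressionDataset(gene_ids=gene_ids, values=values, groups=groups)
    ds.shifted_genes = frozenset(shifted)
    return ds


def crosstalk_fixture(n_cross: int = 5, p_strong: float = 1e-4,
                      p_background: float = 0.5,
                      ) -> tuple[list[PathwayGraph], dict[str, float]]:
    """Two disjoint pathways linked only by strong cross-edges.

    Pathways A and B share no gene; a third (bridge) pathway annotates
    ``n_cross`` directed edges from A's genes into B's genes, as happens in
    pooled canonical collections.  The cross-edge endpoints get direct
    p-value ``p_strong``; every other gene gets ``p_background``.  The pair
    (A, B) then shows a contextual association without any static gene
    overlap.
    """
    a_genes = [f"a{i}" for i in range(1, n_cross + 3)]
    b_genes = [f"b{i}" for i in range(1, n_cross + 3)]
    edges = [InteractionEdge(f"a{i}", f"b{i}", "activation", True)
             for i in range(1, n_cross + 1)]
    graphs = [
        PathwayGraph("A", name="pathway A", genes=set(a_genes)),
        PathwayGraph("B", name="pathway B", genes=set(b_genes)),
        PathwayGraph("BRIDGE", name="bridge", edges=edges),
    ]
    p_direct = {g: p_background for g in a_genes + b_genes}
    for e in edges:
        p_direct[e.source] = p_strong
        p_direct[e.target] = p_strong
    return graphs, p_direct


def generate_null_labels(dataset: ExpressionDataset, seed: int
                         ) -> ExpressionDataset:
    """Shuffle gene identifiers against expression rows.

    The multiset of per-gene values (hence of direct p-values) is unchanged;
    only the gene-to-topology assignment is randomized — the null used for
    false-positive-rate calibration.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(dataset.gene_ids))
    if (perm == np.arange(len(perm))).all():
        logger.info("identity permutation drawn")
    new_ids = [dataset.gene_ids[i] for i in perm]
    return ExpressionDataset(gene_ids=new_ids, values=dataset.values.copy(),
                             groups=dataset.groups.copy())
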