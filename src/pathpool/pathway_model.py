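"""Pathway topology model: per-pathway directed graphs and the pooled adjacency.

Canonical pathway definitions (KGML XML or a plain edge-list dialect) are
parsed into :class:`PathwayGraph` objects and merged into a single
:class:`PooledPathway` — one directed boolean adjacency matrix over the union
of all pathway genes, with per-pathway membership retained.  Pooling makes
inter-pathway edges (a gene in pathway A regulating a gene in pathway B)
available to every downstream score.

Directionality conventions: regulatory interaction subtypes (activation,
inhibition, phosphorylation, ...) become directed edges; binding/association
becomes a bidirectional edge, which contributes both orientations to the
pooled adjacency.  Self-interactions are excluded: the adjacency diagonal is
forced to zero.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

#: How relation subtype labels map onto edge semantics.  Values are
#: "directed", "bidirectional" or "ignore".  Overridable everywhere a
#: relation_map argument is accepted.
DEFAULT_RELATION_MAP: dict[str, str] = {
    "activation": "directed",
    "inhibition": "directed",
    "expression": "directed",
    "repression": "directed",
    "phosphorylation": "directed",
    "dephosphorylation": "directed",
    "ubiquitination": "directed",
    "indirect effect": "directed",
    "binding/association": "bidirectional",
    "dissociation": "ignore",
    "state change": "ignore",
    "missing interaction": "ignore",
}


@dataclass(frozen=True)
class InteractionEdge:
    """One gene-gene interaction inside a pathway."""

    source: str
    target: str
    relation: str
    directed: bool = True


@dataclass
class PathwayGraph:
    """A single pathway: its gene set and interaction edges."""

    pathway_id: str
    name: str = ""
    genes: set[str] = field(default_factory=set)
    edges: list[InteractionEdge] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.edges:
            self.genes.add(e.source)
            self.genes.add(e.target)


@dataclass
class PooledPathway:
    """The merged directed gene graph.

    Attributes
    ----------
    genes : list of str
        Ordered gene universe G.
    adjacency : (len(G), len(G)) bool ndarray
        A[i, j] is True iff some pathway contains an interaction from gene i
        to gene j.  Not symmetric in general; diagonal identically False.
    membership : dict pathway_id -> frozenset of genes
        Measured genes of each pathway (subset of G).  Pathways whose genes
        were all removed by :func:`restrict_to_measured` keep an empty set.
    names : dict pathway_id -> display name
    """

    genes: list[str]
    adjacency: np.ndarray
    membership: "OrderedDict[str, frozenset[str]]"
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def out_degree(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def member_indices(self, pathway_id: str) -> np.ndarray:
        """Sorted adjacency indices of a pathway's measured genes."""
        idx = [self.index[g] for g in self.membership[pathway_id]]
        return np.array(sorted(idx), dtype=np.intp)


class PathwayFormatError(ValueError):
    """Raised on malformed pathway input (XML or edge list)."""


def _classify(relation: str, relation_map: dict[str, str],
              default_policy: str = "ignore") -> str:
    kind = relation_map.get(relation)
    if kind is None:
        logger.warning("unknown relation subtype %r; treating as %s",
                       relation, default_policy)
        kind = default_policy
    if kind not in ("directed", "bidirectional", "ignore"):
        raise ValueError(f"bad relation policy {kind!r} for {relation!r}")
    return kind


def parse_kgml(document: str | bytes, relation_map: dict[str, str] | None = None,
               *, default_policy: str = "ignore",
               source_name: str = "<kgml>") -> PathwayGraph:
    """Parse one KGML document into a :class:`PathwayGraph`.

    Only entries of type ``gene`` become nodes; ``group`` entries are expanded
    to their component genes, with edges replicated to every component.
    Compound-mediated relations (``PCrel``) and ``maplink`` relations are
    skipped — the pooled graph is gene-only.  An entry naming several genes
    yields the full bipartite edge set between the two endpoints' gene lists.
    """
    relation_map = DEFAULT_RELATION_MAP if relation_map is None else relation_map
    try:
        if isinstance(document, str):
            document = document.encode()
        root = etree.fromstring(document)
    except etree.XMLSyntaxError as exc:
        raise PathwayFormatError(f"malformed KGML in {source_name}: {exc}") from exc

    pathway_id = root.get("name", source_name)
    title = root.get("title", "")

    entry_genes: dict[str, list[str]] = {}
    group_components: dict[str, list[str]] = {}
    for entry in root.iter("entry"):
        eid = entry.get("id")
        etype = entry.get("type")
        if etype == "gene":
            entry_genes[eid] = entry.get("name", "").split()
        elif etype == "group":
            group_components[eid] = [c.get("id") for c in entry.iter("component")]

    def genes_of(eid: str) -> list[str]:
        if eid in entry_genes:
            return entry_genes[eid]
        if eid in group_components:
            out: list[str] = []
            for cid in group_components[eid]:
                out.extend(entry_genes.get(cid, []))
            return out
        return []

    genes: set[str] = set()
    for gl in entry_genes.values():
        genes.update(gl)

    edges: list[InteractionEdge] = []
    seen: set[tuple[str, str, str, bool]] = set()
    for rel in root.iter("relation"):
        if rel.get("type") in ("PCrel", "maplink"):
            continue
        src_genes = genes_of(rel.get("entry1"))
        tgt_genes = genes_of(rel.get("entry2"))
        if not src_genes or not tgt_genes:
            continue
        for st in rel.iter("subtype"):
            label = st.get("name", "")
            kind = _classify(label, relation_map, default_policy)
            if kind == "ignore":
                continue
            directed = kind == "directed"
            for s in src_genes:
                for t in tgt_genes:
                    key = (s, t, label, directed)
                    if key not in seen:
                        seen.add(key)
                        edges.append(InteractionEdge(s, t, label, directed))
    return PathwayGraph(pathway_id=pathway_id, name=title, genes=genes, edges=edges)


def read_edge_list(rows, relation_map: dict[str, str] | None = None,
                   *, default_policy: str = "ignore") -> list[PathwayGraph]:
    """Read the 4-column edge-list dialect into per-pathway graphs.

    ``rows`` is a path / file-like readable by pandas, or a DataFrame, with
    columns ``pathway_id, source, target, relation`` (tab-separated, ``#``
    comments).  Duplicate identical rows are dropped with a logged count.
    """
    relation_map = DEFAULT_RELATION_MAP if relation_map is None else relation_map
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.read_csv(rows, sep="\t", comment="#", dtype=str)
    required = ["pathway_id", "source", "target", "relation"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PathwayFormatError(f"edge list missing column(s): {missing}")
    if df.empty:
        raise PathwayFormatError("edge list has no rows")
    n_before = len(df)
    df = df.drop_duplicates(subset=required)
    if len(df) < n_before:
        logger.info("dropped %d duplicate edge rows", n_before - len(df))

    graphs: list[PathwayGraph] = []
    for pid, sub in df.groupby("pathway_id", sort=False):
        edges = []
        for _, r in sub.iterrows():
            kind = _classify(r["relation"], relation_map, default_policy)
            if kind == "ignore":
                continue
            edges.append(InteractionEdge(r["source"], r["target"],
                                         r["relation"], kind == "directed"))
        genes = set(sub["source"]) | set(sub["target"])
        graphs.append(PathwayGraph(pathway_id=str(pid), genes=genes, edges=edges))
    return graphs


def build_pooled(pathways: list[PathwayGraph]) -> PooledPathway:
    """Merge pathway graphs into one pooled adjacency.

    A[i, j] = 1 iff any pathway has an edge i->j, or an undirected edge
    {i, j} (which contributes both orientations).  The adjacency is boolean,
    not a count; the diagonal is forced to zero so self-interactions never
    enter any score.
    """
    if not pathways:
        raise ValueError("build_pooled requires at least one pathway")
    genes: list[str] = []
    seen: set[str] = set()
    for pw in pathways:
        for g in sorted(pw.genes):
            if g not in seen:
                seen.add(g)
                genes.append(g)
    index = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    A = np.zeros((n, n), dtype=bool)
    membership: OrderedDict[str, frozenset[str]] = OrderedDict()
    names: dict[str, str] = {}
    for pw in pathways:
        membership[pw.pathway_id] = frozenset(pw.genes)
        names[pw.pathway_id] = pw.name
        for e in pw.edges:
            i, j = index[e.source], index[e.target]
            A[i, j] = True
            if not e.directed:
                A[j, i] = True
    np.fill_diagonal(A, False)
    return PooledPathway(genes=genes, adjacency=A, membership=membership,
                         names=names)


def restrict_to_measured(pooled: PooledPathway,
                         measured: set[str]) -> PooledPathway:
    """Restrict the pooled graph to experimentally measured genes.

    Rows and columns of unmeasured genes are deleted literally — no
    transitive closure: an i->j->k chain with j unmeasured leaves i and k
    unconnected.  Pathways losing all measured genes are retained with empty
    membership so the output keeps one row per input pathway downstream.
    """
    if not measured:
        raise ValueError("measured gene set is empty")
    keep = [i for i, g in enumerate(pooled.genes) if g in measured]
    if not keep:
        raise ValueError("no pathway gene measured: expression data and "
                         "pathway definitions share no gene identifiers")
    keep_arr = np.array(keep, dtype=np.intp)
    genes = [pooled.genes[i] for i in keep]
    gene_set = set(genes)
    A = pooled.adjacency[np.ix_(keep_arr, keep_arr)].copy()
    membership = OrderedDict(
        (pid, frozenset(m & gene_set)) for pid, m in pooled.membership.items()
    )
    for pid, m in membership.items():
        if not m:
            logger.warning("pathway %s has no measured genes", pid)
    return PooledPathway(genes=genes, adjacency=A, membership=membership,
                         names=dict(pooled.names))


def write_gmt(pooled: PooledPathway, path) -> None:
    """Export pathway membership in GMT format (id, name, genes...)."""
    with open(path, "w") as fh:
        for pid, members in pooled.membership.items():
            name = pooled.names.get(pid, "") or pid
            fh.write("\t".join([pid, name, *sorted(members)]) + "\n")


def read_gmt(path) -> "OrderedDict[str, frozenset[str]]":
    """Read a GMT membership file back into an ordered mapping."""
    out: OrderedDict[str, frozenset[str]] = OrderedDict()
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            out[parts[0]] = frozenset(parts[2:])
    return out
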