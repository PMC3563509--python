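"""Per-gene evidence: direct (t-test), indirect (topology permutation), combined.

Direct evidence p^D is a two-sample t-test p-value per gene.  Indirect
evidence starts from the score

    SI_i = sum_j A_ij * (-log10 p_j^D)

i.e. the differential expression of gene i's neighbours in the pooled
pathway, weighted by connectivity.  Its significance p^I is a permutation
p-value: the p^D values are shuffled over all pooled-pathway genes N times
with the topology held fixed, and p^I counts how often the shuffled score
exceeds the observed one (floored at 1/N, since estimates live on the 1/N
grid).  Direct and indirect p-values are combined with Fisher's method via
the chi-square distribution with 4 degrees of freedom; genes with no
neighbours have no indirect evidence and keep p^C = p^D.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pathway_model import PooledPathway

logger = logging.getLogger(__name__)

_TINY = 1e-300  # clamp for p = 0 before -log10


@dataclass
class ExpressionDataset:
    """Gene x sample expression values with a two-level group factor."""

    gene_ids: list[str]
    values: np.ndarray
    groups: np.ndarray  # length n_samples, exactly two distinct labels

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.groups = np.asarray(self.groups)
        if len(self.gene_ids) != len(set(self.gene_ids)):
            raise ValueError("gene_ids are not unique")
        if self.values.shape != (len(self.gene_ids), len(self.groups)):
            raise ValueError("values shape does not match gene_ids x groups")
        levels, counts = np.unique(self.groups, return_counts=True)
        if len(levels) != 2:
            raise ValueError(f"expected exactly 2 group levels, got {list(levels)}")
        if counts.min() < 2:
            raise ValueError("both groups need >= 2 samples for the t-test")
        self.levels = tuple(levels)


@dataclass
class NullConfig:
    """Permutation-null settings: number of shuffles N and the seed."""

    n_shuffles: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_shuffles < 100:
            raise ValueError("n_shuffles must be >= 100")
        if self.n_shuffles < 1000:
            warnings.warn(f"n_shuffles={self.n_shuffles} is low; permutation "
                          "p-values will be coarse", stacklevel=2)


def direct_evidence(dataset: ExpressionDataset, *,
                    equal_var: bool = False) -> dict[str, float]:
    """Two-sided two-sample t-test p-value per gene (Welch by default).

    Genes with zero variance in both groups and equal means get p = 1;
    any nan from degenerate input is likewise mapped to 1.
    """
    a = dataset.values[:, dataset.groups == dataset.levels[0]]
    b = dataset.values[:, dataset.groups == dataset.levels[1]]
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)  # zero variance in both groups
    same_mean = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p[degenerate & same_mean] = 1.0
    p[degenerate & ~same_mean] = _TINY  # constant but shifted
    p = np.clip(p, _TINY, 1.0)
    return dict(zip(dataset.gene_ids, p.tolist()))


def load_pvalue_table(path) -> dict[str, float]:
    """Plug-in per-gene p-value table (2-column TSV gene -> p) bypassing the t-test."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["gene", "p"], dtype={0: str, 1: float})
    if df["gene"].duplicated().any():
        raise ValueError("duplicate genes in p-value table")
    if ((df["p"] < 0) | (df["p"] > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return dict(zip(df["gene"], df["p"]))


def _weights(pooled: PooledPathway, p_direct: dict[str, float]) -> np.ndarray:
    """-log10 p^D aligned to the pooled gene order, clamping p = 0."""
    p = np.array([p_direct[g] for g in pooled.genes], dtype=float)
    if (p <= 0).any():
        logger.warning("clamping %d nonpositive p-values to %g",
                       int((p <= 0).sum()), _TINY)
        p = np.clip(p, _TINY, None)
    return -np.log10(p)


def _effective_adjacency(pooled: PooledPathway, direction_mode: str) -> np.ndarray:
    """Adjacency orientation used for neighbour sums.

    "literal": out-neighbours (row i of A, the printed formula);
    "in": in-neighbours; "both": union of the two.
    """
    A = pooled.adjacency
    if direction_mode == "literal":
        return A
    if direction_mode == "in":
        return A.T
    if direction_mode == "both":
        return A | A.T
    raise ValueError(f"unknown direction_mode {direction_mode!r}")


def indirect_scores(pooled: PooledPathway, p_direct: dict[str, float],
                    *, direction_mode: str = "literal") -> dict[str, float]:
    """Neighbour-weighted differential-expression score SI per gene."""
    A = _effective_adjacency(pooled, direction_mode)
    si = A.astype(float) @ _weights(pooled, p_direct)
    return dict(zip(pooled.genes, si.tolist()))


def permutation_weight_matrix(weights: np.ndarray, n_shuffles: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Stack of N full permutations of the weight vector, one per column."""
    n = len(weights)
    W = np.empty((n, n_shuffles), dtype=float)
    for k in range(n_shuffles):
        W[:, k] = weights[rng.permutation(n)]
    return W


def indirect_pvalues(pooled: PooledPathway, p_direct: dict[str, float],
                     null: NullConfig, *,
                     direction_mode: str = "literal",
                     ties: str = "gt") -> dict[str, float]:
    """Permutation p-value of SI per connected gene.

    Genes with no neighbours (zero out-degree under the chosen orientation)
    are skipped — they have no indirect evidence.  ``ties="gt"`` counts
    strictly larger shuffled scores; ``ties="ge"`` uses the
    (count + 1) / (N + 1) convention instead.
    """
    A = _effective_adjacency(pooled, direction_mode).astype(float)
    w = _weights(pooled, p_direct)
    si = A @ w
    connected = A.sum(axis=1) > 0
    N = null.n_shuffles
    rng = np.random.default_rng(null.seed)
    W = permutation_weight_matrix(w, N, rng)
    si_rand = A @ W  # genes x N
    if ties == "gt":
        count = (si_rand > si[:, None]).sum(axis=1)
        p = np.maximum(count / N, 1.0 / N)
    elif ties == "ge":
        count = (si_rand >= si[:, None]).sum(axis=1)
        p = (count + 1) / (N + 1)
    else:
        raise ValueError(f"unknown ties convention {ties!r}")
    return {g: float(p[i]) for i, g in enumerate(pooled.genes) if connected[i]}


def combine_evidence(p_direct: dict[str, float], p_indirect: dict[str, float],
                     connected: set[str] | None = None) -> dict[str, float]:
    """Fisher's method on (p^D, p^I) via chi-square with 4 df.

    For a connected gene, p^C is the upper tail of chi2(4) at
    -2 ln(p^D * p^I); for a gene without indirect evidence, p^C = p^D.
    """
    if connected is None:
        connected = set(p_indirect)
    if set(p_indirect) != set(connected):
        raise ValueError("p_indirect must be defined exactly on connected genes")
    out: dict[str, float] = {}
    for g, pd_ in p_direct.items():
        if g in connected:
            stat = -2.0 * (np.log(max(pd_, _TINY)) + np.log(max(p_indirect[g], _TINY)))
            out[g] = float(stats.chi2.sf(stat, df=4))
        else:
            out[g] = pd_
    return out


def evidence_table(pooled: PooledPathway, p_direct: dict[str, float],
                   null: NullConfig, *, alpha: float = 0.05,
                   direction_mode: str = "literal",
                   ties: str = "gt") -> pd.DataFrame:
    """Full per-gene evidence table for the pooled genes.

    Columns: gene, p_direct, si, p_indirect (NaN if unconnected),
    p_combined, connected, significant (p_combined < alpha).
    """
    si = indirect_scores(pooled, p_direct, direction_mode=direction_mode)
    p_ind = indirect_pvalues(pooled, p_direct, null,
                             direction_mode=direction_mode, ties=ties)
    p_comb = combine_evidence({g: p_direct[g] for g in pooled.genes}, p_ind)
    rows = []
    for g in pooled.genes:
        conn = g in p_ind
        rows.append({
            "gene": g,
            "p_direct": p_direct[g],
            "si": si[g],
            "p_indirect": p_ind[g] if conn else np.nan,
            "p_combined": p_comb[g],
            "connected": conn,
            "significant": p_comb[g] < alpha,
        })
    return pd.DataFrame(rows)


def evidence_correlation(table: pd.DataFrame) -> float:
    """Pearson correlation of -log p^D vs -log p^I over connected genes.

    Diagnostic for the independence assumption behind Fisher's method; a
    strong correlation suggests the combined p-values are anti-conservative.
    """
    sub = table[table["connected"]]
    if len(sub) < 3:
        return float("nan")
    x = -np.log10(np.clip(sub["p_direct"].to_numpy(), _TINY, None))
    y = -np.log10(np.clip(sub["p_indirect"].to_numpy(), _TINY, None))
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])
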