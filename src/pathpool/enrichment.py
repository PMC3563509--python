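"""Pathway over-representation of combined-evidence-significant genes.

Genes with p^C < alpha are "significant"; each pathway is tested for an
excess of significant genes with the hypergeometric upper tail P(X >= k)
over the universe of measured pooled-pathway genes.  Raw p-values are
corrected for family-wise error rate (Bonferroni by default, Holm
optionally).  A null-calibration routine re-runs the whole pipeline on
gene-label-shuffled data to estimate empirical false-positive rates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import evidence as ev
from .pathway_model import PooledPathway

logger = logging.getLogger(__name__)


def hypergeom_tail(k: int, K: int, n: int, M: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts successes in ``n`` draws without replacement from a universe of
    ``M`` items of which ``K`` are successes — the convention of R's
    ``phyper(k - 1, K, M - K, n, lower.tail = FALSE)``.
    """
    if not (0 <= k <= min(K, n) and max(K, n) <= M):
        raise ValueError(f"impossible configuration k={k}, K={K}, n={n}, M={M}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def adjust_fwer(p_values, method: str = "bonferroni") -> list[float]:
    """Family-wise error-rate correction (Bonferroni or Holm step-down)."""
    p = np.asarray(list(p_values), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    if len(p) == 0:
        return []
    if method == "bonferroni":
        adj = np.minimum(1.0, len(p) * p)
    elif method == "holm":
        adj = multipletests(p, method="holm")[1]
    else:
        raise ValueError(f"unknown FWER method {method!r}")
    return adj.tolist()


def enrich(evidence_table: pd.DataFrame, pooled: PooledPathway,
           alpha: float = 0.05, *, fwer_method: str = "bonferroni") -> pd.DataFrame:
    """Hypergeometric enrichment, one row per pathway.

    Universe = measured pooled-pathway genes; draws = significant genes
    (p^C < alpha, strict).  Pathways with zero measured genes get p_raw = 1
    and are flagged.  Rows are sorted by (p_fwer, p_raw, pathway_id).
    """
    table = evidence_table.set_index("gene")
    missing = [g for g in pooled.genes if g not in table.index]
    if missing:
        raise ValueError(f"evidence table does not cover {len(missing)} pooled genes")
    sig = set(table.index[table["p_combined"] < alpha]) & set(pooled.genes)
    n_universe = pooled.n_genes
    n_sig_universe = len(sig)
    if n_sig_universe == 0:
        logger.warning("no significant genes at alpha=%g; all p_raw = 1", alpha)
    rows = []
    for pid, members in pooled.membership.items():
        n_pathway = len(members)
        n_sig_pathway = len(members & sig)
        if n_pathway == 0:
            p_raw, empty = 1.0, True
        else:
            p_raw = hypergeom_tail(n_sig_pathway, n_pathway,
                                   n_sig_universe, n_universe)
            empty = False
        rows.append({
            "pathway_id": pid,
            "name": pooled.names.get(pid, ""),
            "n_universe": n_universe,
            "n_sig_universe": n_sig_universe,
            "n_pathway": n_pathway,
            "n_sig_pathway": n_sig_pathway,
            "p_raw": p_raw,
            "no_measured_genes": empty,
        })
    df = pd.DataFrame(rows)
    df["p_fwer"] = adjust_fwer(df["p_raw"], method=fwer_method)
    df = df.sort_values(["p_fwer", "p_raw", "pathway_id"],
                        kind="mergesort").reset_index(drop=True)
    return df


def run_pipeline(pooled: PooledPathway, p_direct: dict[str, float],
                 null: ev.NullConfig, *, alpha: float = 0.05,
                 fwer_method: str = "bonferroni",
                 direction_mode: str = "literal",
                 ties: str = "gt") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evidence table + enrichment table from direct p-values on a pooled graph."""
    table = ev.evidence_table(pooled, p_direct, null, alpha=alpha,
                              direction_mode=direction_mode, ties=ties)
    return table, enrich(table, pooled, alpha, fwer_method=fwer_method)


def null_calibration(dataset: "ev.ExpressionDataset", pooled: PooledPathway,
                     n_randomizations: int, null: ev.NullConfig,
                     *, alpha: float = 0.05, cutoff: float = 0.05,
                     fwer_method: str = "bonferroni",
                     direction_mode: str = "literal") -> dict:
    """False-positive-rate estimate from gene-label shuffling.

    Gene identifiers are permuted against the expression rows, which keeps
    the multiset of direct p-values and the topology fixed while destroying
    any gene-topology alignment; the full pipeline is re-run on each
    randomization.  Returns the indicator matrix (randomizations x pathways)
    of p_fwer < cutoff, the overall rate, and per-pathway rates.
    """
    p_direct = ev.direct_evidence(dataset)
    common = [g for g in dataset.gene_ids if g in pooled.index]
    p_vec = np.array([p_direct[g] for g in common])
    rng = np.random.default_rng(null.seed)
    pids = list(pooled.membership)
    indicators = np.zeros((n_randomizations, len(pids)), dtype=bool)
    for r in range(n_randomizations):
        shuffled = dict(zip(common, p_vec[rng.permutation(len(common))]))
        # unmeasured pooled genes keep p = 1 so the shuffle stays within data
        full = {g: shuffled.get(g, 1.0) for g in pooled.genes}
        sub_null = ev.NullConfig(null.n_shuffles,
                                 seed=int(rng.integers(2**31 - 1)))
        _, enr = run_pipeline(pooled, full, sub_null, alpha=alpha,
                              fwer_method=fwer_method,
                              direction_mode=direction_mode)
        enr = enr.set_index("pathway_id")
        indicators[r] = [enr.loc[p, "p_fwer"] < cutoff for p in pids]
    per_pathway = indicators.mean(axis=0)
    return {
        "n_randomizations": n_randomizations,
        "cutoff": cutoff,
        "overall_fpr": float(indicators.mean()),
        "per_pathway_fpr": dict(zip(pids, per_pathway.tolist())),
        "max_pathway_fpr": float(per_pathway.max()),
        "indicators": indicators,
    }
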