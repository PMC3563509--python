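"""Direct, indirect and combined per-gene evidence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from conftest import exact_permutation_pvalues, fisher_two_oracle
from pathpool.evidence import (ExpressionDataset, NullConfig, combine_evidence,
                               direct_evidence, evidence_table,
                               indirect_pvalues, indirect_scores)
from pathpool.pathway_model import (InteractionEdge, PathwayGraph,
                                    build_pooled)


def make_dataset(values, groups):
    values = np.asarray(values, dtype=float)
    return ExpressionDataset(gene_ids=[f"g{i}" for i in range(len(values))],
                             values=values, groups=np.asarray(groups))


class TestDirectEvidence:
    def test_identical_groups_give_p_one(self):
        ds = make_dataset([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]],
                          ["c", "c", "c", "d", "d", "d"])
        assert direct_evidence(ds)["g0"] == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(20, 8))
        p1 = direct_evidence(make_dataset(vals, ["c"] * 4 + ["d"] * 4))
        p2 = direct_evidence(make_dataset(vals, ["d"] * 4 + ["c"] * 4))
        assert p1 == p2

    def test_matches_welch_reference(self):
        a, b = [1.0, 1.2, 0.9], [2.0, 2.1, 1.9]
        ds = make_dataset([a + b], ["c"] * 3 + ["d"] * 3)
        # independent reference: Welch statistic + t CDF by hand
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        se2 = va / 3 + vb / 3
        t = (np.mean(a) - np.mean(b)) / np.sqrt(se2)
        df = se2 ** 2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        expected = 2 * stats.t.sf(abs(t), df)
        assert direct_evidence(ds)["g0"] == pytest.approx(expected, rel=1e-12)

    def test_constant_shifted_gene_is_maximally_significant(self):
        ds = make_dataset([[1, 1, 1, 2, 2, 2]], ["c"] * 3 + ["d"] * 3)
        assert direct_evidence(ds)["g0"] < 1e-100

    def test_single_sample_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2 samples"):
            make_dataset([[1, 2, 3]], ["c", "c", "d"])


class TestIndirectScores:
    def test_arithmetic(self, chain_pooled):
        # chain a->b->c plus undirected {c,d}
        p = {"a": 1.0, "b": 1e-3, "c": 0.1, "d": 0.01}
        si = indirect_scores(chain_pooled, p)
        assert si["a"] == pytest.approx(3.0)       # -log10 p_b
        assert si["b"] == pytest.approx(1.0)       # -log10 p_c
        assert si["c"] == pytest.approx(2.0)       # -log10 p_d
        assert si["d"] == pytest.approx(1.0)       # -log10 p_c

    def test_additivity_over_out_neighbours(self):
        pooled = build_pooled([PathwayGraph("P", edges=[
            InteractionEdge("i", "j", "x"), InteractionEdge("i", "k", "x")])])
        si = indirect_scores(pooled, {"i": 1.0, "j": 0.1, "k": 0.01})
        assert si["i"] == pytest.approx(3.0)

    def test_no_outgoing_edges_gives_zero(self, chain_pooled):
        si = indirect_scores(chain_pooled, {g: 0.5 for g in chain_pooled.genes})
        # 'a' has no in-edges but one out-edge; nothing points out of... none here
        assert min(si.values()) >= 0

    def test_zero_pvalue_clamped(self, chain_pooled):
        p = {"a": 1.0, "b": 0.0, "c": 0.5, "d": 0.5}
        si = indirect_scores(chain_pooled, p)
        assert np.isfinite(si["a"]) and si["a"] > 100

    def test_direction_modes(self):
        pooled = build_pooled([PathwayGraph("P", edges=[
            InteractionEdge("i", "j", "x")])])
        p = {"i": 0.1, "j": 0.01}
        assert indirect_scores(pooled, p)["i"] == pytest.approx(2.0)
        assert indirect_scores(pooled, p, direction_mode="in")["j"] == \
            pytest.approx(1.0)
        both = indirect_scores(pooled, p, direction_mode="both")
        assert both["i"] == pytest.approx(2.0) and both["j"] == pytest.approx(1.0)


class TestIndirectPvalues:
    def test_identical_pd_hits_floor(self, chain_pooled):
        null = NullConfig(2000, seed=1)
        p = indirect_pvalues(chain_pooled, {g: 0.2 for g in chain_pooled.genes},
                             null)
        assert all(v == pytest.approx(1 / 2000) for v in p.values())

    def test_grid_and_floor(self, chain_pooled, tiny_rng):
        null = NullConfig(2000, seed=7)
        pd_map = dict(zip(chain_pooled.genes, tiny_rng.uniform(0.001, 1, 4)))
        pv = indirect_pvalues(chain_pooled, pd_map, null)
        for v in pv.values():
            assert v >= 1 / 2000 - 1e-12
            assert round(v * 2000) == pytest.approx(v * 2000, abs=1e-9)

    def test_zero_outdegree_genes_skipped(self, chain_pooled):
        pv = indirect_pvalues(chain_pooled,
                              {g: 0.3 for g in chain_pooled.genes},
                              NullConfig(500, seed=0))
        assert "b" in pv and "a" in pv  # a->b, b->c have out-edges
        # 'd' has out-edge d->c (binding is bidirectional): included too
        assert set(pv) == {"a", "b", "c", "d"}

    def test_matches_exhaustive_enumeration(self):
        """Monte-Carlo p^I within 3 binomial SE of the exact 4!-permutation value."""
        pooled = build_pooled([PathwayGraph("P", edges=[
            InteractionEdge("a", "b", "x"), InteractionEdge("a", "c", "x"),
            InteractionEdge("b", "c", "x"), InteractionEdge("c", "d", "x")])])
        pd_map = {"a": 0.5, "b": 0.01, "c": 0.2, "d": 0.9}
        w = -np.log10([pd_map[g] for g in pooled.genes])
        exact = exact_permutation_pvalues(pooled.adjacency, w)
        N = 2000
        mc = indirect_pvalues(pooled, pd_map, NullConfig(N, seed=11))
        for i, g in enumerate(pooled.genes):
            if g not in mc:
                continue
            se = np.sqrt(exact[i] * (1 - exact[i]) / N)
            assert abs(mc[g] - max(exact[i], 1 / N)) <= 3 * se + 1 / N

    def test_determinism(self, chain_pooled, tiny_rng):
        pd_map = dict(zip(chain_pooled.genes, tiny_rng.uniform(0.01, 1, 4)))
        a = indirect_pvalues(chain_pooled, pd_map, NullConfig(500, seed=3))
        b = indirect_pvalues(chain_pooled, pd_map, NullConfig(500, seed=3))
        assert a == b

    def test_low_shuffle_count_warns(self):
        with pytest.warns(UserWarning, match="coarse"):
            NullConfig(200, seed=0)
        with pytest.raises(ValueError):
            NullConfig(50, seed=0)


class TestCombineEvidence:
    def test_degenerate_unit_pvalues(self):
        out = combine_evidence({"g": 1.0}, {"g": 1.0})
        assert out["g"] == pytest.approx(1.0)

    def test_closed_form_example(self):
        out = combine_evidence({"g": 0.1}, {"g": 0.1})
        assert out["g"] == pytest.approx(0.0561, abs=5e-4)
        assert out["g"] == pytest.approx(fisher_two_oracle(0.1, 0.1), rel=1e-10)

    def test_isolated_gene_keeps_direct_pvalue(self):
        out = combine_evidence({"iso": 0.03, "conn": 0.5}, {"conn": 0.2})
        assert out["iso"] == 0.03

    def test_mismatched_connected_set_rejected(self):
        with pytest.raises(ValueError):
            combine_evidence({"a": 0.5}, {"a": 0.5}, connected={"a", "b"})

    @settings(max_examples=200, deadline=None)
    @given(st.floats(1e-12, 1.0), st.floats(1e-12, 1.0))
    def test_fisher_closed_form_equivalence(self, p1, p2):
        """chi2(4df) upper tail at -2 ln(p1 p2) equals q(1 - ln q)."""
        out = combine_evidence({"g": p1}, {"g": p2})
        assert out["g"] == pytest.approx(fisher_two_oracle(p1, p2), rel=1e-10)


class TestEvidenceTable:
    def test_schema_and_consistency(self, chain_pooled, tiny_rng):
        pd_map = dict(zip(chain_pooled.genes, tiny_rng.uniform(0.001, 1, 4)))
        tab = evidence_table(chain_pooled, pd_map, NullConfig(500, seed=1))
        assert list(tab["gene"]) == chain_pooled.genes
        disc = tab[~tab["connected"]]
        assert (disc["p_combined"] == disc["p_direct"]).all()
        assert tab["p_indirect"].notna().equals(tab["connected"])
        assert ((tab["p_combined"] > 0) & (tab["p_combined"] <= 1)).all()

    def test_bitwise_reproducible(self, chain_pooled, tiny_rng):
        pd_map = dict(zip(chain_pooled.genes, tiny_rng.uniform(0.001, 1, 4)))
        t1 = evidence_table(chain_pooled, pd_map, NullConfig(500, seed=9))
        t2 = evidence_table(chain_pooled, pd_map, NullConfig(500, seed=9))
        assert t1.equals(t2)


def test_monotonicity_of_si_and_exact_pvalue():
    """Lowering a neighbour's p^D raises SI and lowers the exact p^I."""
    pooled = build_pooled([PathwayGraph("P", edges=[
        InteractionEdge("a", "b", "x"), InteractionEdge("a", "c", "x"),
        InteractionEdge("d", "b", "x")])])
    base = {"a": 0.5, "b": 0.3, "c": 0.2, "d": 0.9}
    lower = dict(base, b=0.01)
    si0 = indirect_scores(pooled, base)
    si1 = indirect_scores(pooled, lower)
    assert si1["a"] > si0["a"] and si1["d"] > si0["d"]
    ia = pooled.index["a"]
    w0 = -np.log10([base[g] for g in pooled.genes])
    w1 = -np.log10([lower[g] for g in pooled.genes])
    e0 = exact_permutation_pvalues(pooled.adjacency, w0)[ia]
    e1 = exact_permutation_pvalues(pooled.adjacency, w1)[ia]
    assert e1 <= e0


def test_permutation_pvalues_valid_under_global_null():
    """Under i.i.d. uniform p^D, p^I is stochastically >= uniform on the grid."""
    rng = np.random.default_rng(42)
    n = 200
    genes = [f"g{i}" for i in range(n)]
    edges = [InteractionEdge(genes[i], genes[rng.integers(n)], "x")
             for i in range(n) for _ in range(3)]
    pooled = build_pooled([PathwayGraph("P", genes=set(genes), edges=edges)])
    pd_map = dict(zip(pooled.genes, rng.uniform(size=pooled.n_genes)))
    pv = np.array(list(indirect_pvalues(pooled, pd_map,
                                        NullConfig(1000, seed=5)).values()))
    # one-sided check: empirical CDF never exceeds uniform by a wide margin
    for q in (0.05, 0.1, 0.25, 0.5):
        frac = (pv <= q).mean()
        se = np.sqrt(q * (1 - q) / len(pv))
        assert frac <= q + 3 * se
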