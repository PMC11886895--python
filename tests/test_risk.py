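"""Disease-set assembly, risk extraction, topology, and enrichment."""

import itertools

import networkx as nx
import numpy as np
import pytest

from cernarisk import risk
from cernarisk.models import CeRNAPair

from oracles import (
    enumerate_shortest_path_betweenness,
    exact_mannwhitney_greater,
    hypergeom_tail_by_enumeration,
)


def pair(c, g, mirnas=("m1", "m2", "m3")):
    return CeRNAPair(c, g, frozenset(mirnas))


class TestAssembleDiseaseSets:
    def test_flag_union(self):
        anns = risk.assemble_disease_sets(gwas_gene=["g1"], de_gene=["g1"])
        assert len(anns) == 1 and anns[0].flags == {"gwas", "de"}

    def test_empty(self):
        assert risk.assemble_disease_sets() == []

    def test_class_counts_inclusion_exclusion(self):
        rng = np.random.default_rng(0)
        ids = [f"g{i}" for i in range(40)]
        gwas = {i for i in ids if rng.random() < 0.4}
        known = {i for i in ids if rng.random() < 0.4}
        de = {i for i in ids if rng.random() < 0.4}
        anns = risk.assemble_disease_sets(gwas_gene=gwas, known_gene=known, de_gene=de)
        assert risk.annotation_counts(anns)["gene"] == len(gwas | known | de)
        for a in anns:
            expected = {f for f, s in (("gwas", gwas), ("known", known), ("de", de))
                        if a.feature_id in s}
            assert a.flags == expected


class TestExtractRiskNetwork:
    def test_unannotated_pair_dropped_annotated_kept(self):
        pairs = [pair("c1", "g1"), pair("c2", "g2")]
        anns = risk.assemble_disease_sets(known_circ=["c1"])
        net = risk.extract_risk_network(pairs, anns)
        assert [e.circ_id for e in net.edges] == ["c1"]

    def test_full_annotation_keeps_all_empty_keeps_none(self):
        pairs = [pair(f"c{i}", f"g{i}") for i in range(5)]
        all_ann = risk.assemble_disease_sets(
            known_circ=[p.circ_id for p in pairs], known_gene=[p.gene_id for p in pairs])
        assert len(risk.extract_risk_network(pairs, all_ann).edges) == 5
        assert risk.extract_risk_network(pairs, []).edges == []

    def test_mirna_annotations_do_not_drive_retention(self):
        pairs = [pair("c1", "g1")]
        anns = risk.assemble_disease_sets(known_mirna=["m1"])
        assert risk.extract_risk_network(pairs, anns).edges == []

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            pairs = [pair(f"c{rng.integers(10)}", f"g{rng.integers(10)}")
                     for _ in range(rng.integers(1, 30))]
            ann_circ = {f"c{i}" for i in range(10) if rng.random() < 0.3}
            ann_gene = {f"g{i}" for i in range(10) if rng.random() < 0.3}
            anns = risk.assemble_disease_sets(known_circ=ann_circ, known_gene=ann_gene)
            got = {(e.circ_id, e.gene_id)
                   for e in risk.extract_risk_network(pairs, anns).edges}
            expected = {(p.circ_id, p.gene_id) for p in pairs
                        if p.circ_id in ann_circ or p.gene_id in ann_gene}
            assert got == expected

    def test_degree_sum_is_twice_edges(self):
        rng = np.random.default_rng(2)
        pairs = list({(f"c{rng.integers(8)}", f"g{rng.integers(8)}")
                      for _ in range(30)})
        pairs = [pair(c, g) for c, g in pairs]
        deg = risk.node_degree(pairs)
        assert sum(deg.values()) == 2 * len(pairs)


class TestCentrality:
    def test_path_graph_closed_form(self):
        g = nx.path_graph(["a", "b", "c"])
        assert risk.node_degree(g)["b"] == 2
        bet = risk.node_betweenness(g)
        assert bet == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_triangle_all_zero(self):
        g = nx.cycle_graph(3)
        assert set(risk.node_betweenness(g).values()) == {0.0}

    def test_betweenness_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(4, 31))
            nodes = list(range(n))
            edges = [(i, j) for i, j in itertools.combinations(nodes, 2)
                     if rng.random() < 0.15]
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            got = risk.node_betweenness(g)
            expected = enumerate_shortest_path_betweenness(edges, nodes)
            for v in nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-9)


class TestCompareTopology:
    def test_exact_shift_example(self):
        from scipy.stats import mannwhitneyu

        # fully separated groups of 3: U = 9 and the exact tail is 1/20
        u0, p0 = exact_mannwhitney_greater([10, 11, 12], [1, 2, 3])
        assert u0 == 9 and p0 == pytest.approx(1 / 20)
        u, p = mannwhitneyu([10, 11, 12], [1, 2, 3],
                            alternative="greater", method="auto")
        assert u == 9 and p == pytest.approx(1 / 20)

    def test_matches_exact_permutation_null_small_groups(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(5)
        for _ in range(30):
            n1, n2 = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            # continuous values: no ties, scipy uses the exact null
            x = rng.normal(size=n1).tolist()
            y = rng.normal(size=n2).tolist()
            u, p = mannwhitneyu(x, y, alternative="greater", method="auto")
            u0, p0 = exact_mannwhitney_greater(x, y)
            assert u == pytest.approx(u0)
            assert p == pytest.approx(p0, abs=1e-12)

    def test_no_shift_p_values_not_skewed_small(self):
        # random disease subsets carry no degree shift: the one-sided p
        # should look roughly uniform, not concentrated near 0
        g = nx.gnm_random_graph(60, 120, seed=11)
        rng = np.random.default_rng(12)
        ps = []
        for _ in range(60):
            disease = [int(i) for i in rng.choice(60, size=20, replace=False)]
            ps.append(risk.compare_topology(g, disease, "degree").p_value)
        assert 0.25 < np.median(ps) < 0.75
        assert np.mean(np.array(ps) < 0.05) <= 0.2
        # fully tied metric values degenerate to p = 1 (no evidence of shift)
        cycle = nx.cycle_graph(10)
        assert risk.compare_topology(cycle, [0, 1, 2], "degree").p_value == 1.0

    def test_planted_hubs_significant(self):
        rng = np.random.default_rng(6)
        g = nx.gnm_random_graph(60, 120, seed=3)
        hubs = list(range(6))
        for h in hubs:  # inflate hub degree ~5x
            for t in rng.choice(range(6, 60), size=15, replace=False):
                g.add_edge(h, int(t))
        cmp = risk.compare_topology(g, hubs, "degree")
        assert cmp.p_value < 0.01
        cmp_b = risk.compare_topology(g, hubs, "betweenness")
        assert cmp_b.p_value < 0.01

    def test_empty_group_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            risk.compare_topology(g, [], "degree")
        with pytest.raises(ValueError):
            risk.compare_topology(g, list(g.nodes), "degree")


class TestEnrichment:
    def test_hand_computed_tail(self):
        universe = [f"g{i}" for i in range(10)]
        term = {"T": set(universe[:5])}
        res = risk.enrich(universe[:4], term, universe)
        # N=10, K=5, n=4, k=4 -> C(5,4)C(5,0)/C(10,4) = 5/210
        assert res[0].p_value == pytest.approx(5 / 210)

    def test_zero_overlap_p_is_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = risk.enrich(universe[5:9], {"T": set(universe[:5])}, universe)
        r = res[0]
        assert r.overlap_k == 0 and r.p_value == pytest.approx(1.0)

    def test_query_equals_universe(self):
        universe = [f"g{i}" for i in range(8)]
        res = risk.enrich(universe, {"T": set(universe[:3])}, universe)
        assert res[0].overlap_k == 3 and res[0].p_value == pytest.approx(1.0)

    def test_matches_exhaustive_draw_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            N = int(rng.integers(3, 13))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            universe = [f"g{i}" for i in range(N)]
            query = [universe[int(i)] for i in rng.choice(N, size=n, replace=False)]
            term = {"T": set(universe[:K])}
            res = risk.enrich(query, term, universe)
            k = res[0].overlap_k
            assert res[0].p_value == pytest.approx(
                hypergeom_tail_by_enumeration(N, K, n, k), abs=1e-12)

    def test_fdr_at_least_p_and_ordering(self):
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(50)]
        terms = {f"T{j}": {universe[int(i)]
                           for i in rng.choice(50, size=10, replace=False)}
                 for j in range(8)}
        res = risk.enrich(universe[:15], terms, universe)
        assert all(r.fdr >= r.p_value - 1e-12 for r in res)
        assert [r.p_value for r in res] == sorted(r.p_value for r in res)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            risk.enrich([], {"T": {"g"}}, [])

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            risk.enrich(["x"], {"T": {"g"}}, ["g"])
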