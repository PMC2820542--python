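"""Subnetwork extraction, hypergeometric linker test, and BH adjustment."""

import random

import networkx as nx
import pytest

from altnet import graph as gr
from altnet.extraction import bh_adjust, extract_network, linker_pvalue

from conftest import bh_stepup_by_hand, hypergeom_upper_tail


class TestLinkerPvalue:
    def test_small_exact_value(self):
        # 3 draws from 9 (candidate excluded), 4 altered, all 3 altered:
        # C(4,3)*C(5,0)/C(9,3) = 4/84
        assert linker_pvalue(3, 3, 10, 4) == pytest.approx(4 / 84, abs=1e-12)

    def test_zero_successes_is_certain(self):
        for n, N, K in [(1, 5, 2), (4, 9, 3), (7, 20, 0)]:
            assert linker_pvalue(n, 0, N, K) == pytest.approx(1.0)

    def test_all_population_altered(self):
        assert linker_pvalue(2, 2, 6, 5) == pytest.approx(1.0)

    def test_invalid_arguments_raise(self):
        with pytest.raises(ValueError):
            linker_pvalue(3, 4, 10, 4)  # k > n
        with pytest.raises(ValueError):
            linker_pvalue(10, 2, 10, 4)  # n > N - 1

    def test_matches_enumeration_oracle_small(self):
        for N in (4, 6, 9):
            for K in range(N):
                for n in range(1, N):
                    for k in range(0, min(n, K) + 1):
                        assert linker_pvalue(n, k, N, K) == pytest.approx(
                            hypergeom_upper_tail(n, k, N, K), abs=1e-12
                        )


class TestBH:
    def test_hand_worked_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_and_degenerate(self):
        assert bh_adjust([0.5]) == [0.5]
        assert bh_adjust([1.0, 1.0]) == [1.0, 1.0]
        assert bh_adjust([]) == []

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])

    def test_matches_stepup_oracle(self):
        rng = random.Random(42)
        for _ in range(50):
            p = [rng.random() for _ in range(rng.randint(1, 20))]
            assert bh_adjust(p) == pytest.approx(bh_stepup_by_hand(p), abs=1e-12)


def star_hin():
    """Altered A, B joined through hub X; Y dangles off one altered gene."""
    hin = gr.new_network()
    for a, b in [("A", "X"), ("B", "X"), ("A", "Y"), ("A", "B")]:
        gr.add_edge(hin, a, b)
    return hin


class TestExtractNetwork:
    def test_direct_connection_sp1(self):
        hin = star_hin()
        ext = extract_network(hin, {"A", "B"}, sp_threshold=1)
        assert set(ext.graph.edges) == {("A", "B")}
        assert ext.linker_stats == []

    def test_sp1_equals_induced_subgraph(self):
        rng = random.Random(5)
        for _ in range(20):
            g = nx.gnp_random_graph(12, 0.3, seed=rng.randint(0, 10**6))
            g = nx.relabel_nodes(g, {i: f"g{i}" for i in g.nodes})
            altered = set(rng.sample(sorted(g.nodes), 5))
            ext = extract_network(g, altered, sp_threshold=1)
            induced = g.subgraph(altered)
            assert set(map(frozenset, ext.graph.edges)) == set(
                map(frozenset, induced.edges)
            )

    def test_linker_connecting_two_altered_retained(self):
        # X joins both altered genes; background nodes make that surprising:
        # p = C(2,2)/C(7,2) = 1/21 < 0.05
        hin = gr.new_network()
        for a, b in [("A", "X"), ("B", "X")]:
            gr.add_edge(hin, a, b)
        hin.add_nodes_from(f"Y{i}" for i in range(5))
        ext = extract_network(hin, {"A", "B"}, fdr_cutoff=0.05)
        assert ext.roles == {"A": "ALTERED", "B": "ALTERED", "X": "LINKER"}
        assert ext.graph.degree["X"] == 2
        assert ext.linker_stats[0].p_value == pytest.approx(1 / 21)

    def test_degree_one_neighbor_never_tested(self):
        hin = star_hin()
        ext = extract_network(hin, {"A", "B"}, fdr_cutoff=1.0)
        assert all(c.gene != "Y" for c in ext.candidates)
        assert "Y" not in ext.graph

    def test_every_linker_has_two_altered_neighbors(self):
        rng = random.Random(9)
        for _ in range(10):
            g = nx.gnp_random_graph(40, 0.12, seed=rng.randint(0, 10**6))
            g = nx.relabel_nodes(g, {i: f"g{i:02d}" for i in g.nodes})
            altered = set(rng.sample(sorted(g.nodes), 10))
            ext = extract_network(g, altered, fdr_cutoff=0.5)
            for c in ext.linker_stats:
                nbrs = set(ext.graph.neighbors(c.gene)) & altered
                assert len(nbrs) >= 2

    def test_lowering_fdr_is_monotone(self):
        rng = random.Random(11)
        g = nx.gnp_random_graph(50, 0.15, seed=3)
        g = nx.relabel_nodes(g, {i: f"g{i:02d}" for i in g.nodes})
        altered = set(rng.sample(sorted(g.nodes), 12))
        prev = None
        for cutoff in (1.0, 0.5, 0.1, 0.01):
            kept = {c.gene for c in extract_network(g, altered, fdr_cutoff=cutoff).linker_stats}
            if prev is not None:
                assert kept <= prev
            prev = kept

    def test_linker_linker_edges_added(self):
        # X and Z both link A and B and interact with each other; background
        # nodes keep their enrichment p-values below the cutoff
        hin = gr.new_network()
        for a, b in [("A", "X"), ("B", "X"), ("A", "Z"), ("B", "Z"), ("X", "Z")]:
            gr.add_edge(hin, a, b)
        hin.add_nodes_from(f"Y{i}" for i in range(6))
        ext = extract_network(hin, {"A", "B"}, fdr_cutoff=0.1)
        assert {c.gene for c in ext.linker_stats} == {"X", "Z"}
        assert ext.graph.has_edge("X", "Z")

    def test_unplaced_altered_genes_reported_not_isolated(self):
        hin = gr.new_network()
        gr.add_edge(hin, "A", "B")
        hin.add_node("LONER")
        ext = extract_network(hin, {"A", "B", "LONER"})
        assert "LONER" not in ext.graph
        assert ext.unplaced == ["LONER"]

    def test_empty_intersection_warns_empty_network(self):
        hin = gr.new_network()
        gr.add_edge(hin, "A", "B")
        ext = extract_network(hin, {"Q", "R"})
        assert ext.graph.number_of_nodes() == 0 and ext.unplaced == []

    def test_order_invariance(self):
        g = nx.gnp_random_graph(30, 0.2, seed=8)
        g = nx.relabel_nodes(g, {i: f"g{i:02d}" for i in g.nodes})
        altered = {"g00", "g05", "g10", "g15", "g20"}
        e1 = extract_network(g, set(sorted(altered)))
        e2 = extract_network(g, set(reversed(sorted(altered))))
        assert set(e1.graph.edges) == set(e2.graph.edges)
        assert e1.linker_stats == e2.linker_stats
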