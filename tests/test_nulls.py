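"""Degree-preserving rewiring and the two permutation null models."""

import random

import networkx as nx
import pytest

from altnet import graph as gr
from altnet.modules import girvan_newman
from altnet.nulls import global_null, local_null, rewire, scaled_modularity
from altnet.synth import plant_modules, synth_hin

from conftest import random_simple_graph


class TestScaledModularity:
    def test_worked_example(self):
        assert scaled_modularity(0.519, 0.296, 0.058) == pytest.approx(3.84, abs=0.005)

    def test_observed_at_mean_is_zero(self):
        assert scaled_modularity(0.3, 0.3, 0.01) == 0.0

    def test_degenerate_null_raises(self):
        with pytest.raises(ValueError):
            scaled_modularity(0.5, 0.3, 0.0)


class TestRewire:
    def test_degree_sequence_and_simplicity_preserved(self):
        rng = random.Random(314)
        for i in range(20):
            g = random_simple_graph(rng, n_max=15)
            if g.number_of_edges() < 2:
                continue
            r = rewire(g, swap_multiplier=5, seed=i)
            assert set(r.nodes) == set(g.nodes)
            assert r.number_of_edges() == g.number_of_edges()
            assert dict(r.degree) == dict(g.degree)
            assert all(u != v for u, v in r.edges)

    def test_path_with_no_valid_swap_returns_copy(self):
        g = nx.path_graph(["a", "b", "c"])
        with pytest.warns(UserWarning):
            r = rewire(g, swap_multiplier=2, seed=0)
        assert set(map(frozenset, r.edges)) == set(map(frozenset, g.edges))

    def test_seeds_change_topology_not_degrees(self):
        g = nx.cycle_graph(range(6))
        g.add_edge(0, 3)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        seen = {frozenset(map(frozenset, rewire(g, 10, seed=s).edges)) for s in range(8)}
        assert len(seen) > 1
        for s in range(8):
            assert dict(rewire(g, 10, seed=s).degree) == dict(g.degree)

    def test_reproducible_per_seed(self):
        g = nx.gnp_random_graph(12, 0.4, seed=1)
        e1 = set(rewire(g, 10, seed=5).edges)
        e2 = set(rewire(g, 10, seed=5).edges)
        assert e1 == e2

    def test_too_few_edges_raise(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(ValueError):
            rewire(g, seed=0)


class TestGlobalNull:
    def hin(self):
        net = synth_hin(60, 4.0, "ER", seed=21)
        return net

    def test_empirical_p_counts_meet_or_exceed(self):
        hin = self.hin()
        # an unbeatable observation gives p = 0; a trivial one gives p = 1
        s_hi = global_null(hin, 8, observed=(10**6, 10**6), iterations=20, seed=4)
        s_lo = global_null(hin, 8, observed=(0, 0), iterations=20, seed=4)
        assert s_hi.p_nodes == 0.0 and s_hi.p_edges == 0.0
        assert s_lo.p_nodes == 1.0 and s_lo.p_edges == 1.0
        assert s_hi.format_p(s_hi.p_nodes) == "< 0.05"

    def test_p_has_iteration_granularity(self):
        hin = self.hin()
        s = global_null(hin, 10, observed=(3, 2), iterations=25, seed=7)
        assert (s.p_nodes * 25) == pytest.approx(round(s.p_nodes * 25))
        assert 0.0 <= s.p_nodes <= 1.0 and 0.0 <= s.p_edges <= 1.0

    def test_single_iteration_equal_draw(self):
        hin = self.hin()
        probe = global_null(hin, 6, observed=(0, 0), iterations=1, seed=3)
        n, e = probe.null_values[0]
        again = global_null(hin, 6, observed=(n, e), iterations=1, seed=3)
        assert again.p_nodes == 1.0 and again.p_edges == 1.0

    def test_oversized_sample_raises(self):
        with pytest.raises(ValueError):
            global_null(self.hin(), 10**4, observed=(1, 1), iterations=1, seed=0)

    def test_reproducible_and_seed_sensitive(self):
        hin = self.hin()
        a = global_null(hin, 8, observed=(5, 4), iterations=15, seed=11)
        b = global_null(hin, 8, observed=(5, 4), iterations=15, seed=11)
        c = global_null(hin, 8, observed=(5, 4), iterations=15, seed=12)
        assert a.null_values == b.null_values
        assert a.null_values != c.null_values


class TestLocalNull:
    def test_structured_graph_scores_high_random_graph_low(self, bridged_cliques):
        part = girvan_newman(bridged_cliques)
        s = local_null(bridged_cliques, part.q, iterations=30, seed=2)
        assert s.z is not None and s.z > 2.0

        er = nx.gnp_random_graph(16, 0.35, seed=6)
        er = nx.relabel_nodes(er, {i: f"n{i}" for i in er.nodes})
        er_part = girvan_newman(er)
        s_er = local_null(er, er_part.q, iterations=30, seed=2)
        assert s_er.z is not None and abs(s_er.z) < 3.0

    def test_mean_sd_match_null_values(self, bridged_cliques):
        import numpy as np

        part = girvan_newman(bridged_cliques)
        s = local_null(bridged_cliques, part.q, iterations=10, seed=9)
        assert s.mean == pytest.approx(np.mean(s.null_values))
        assert s.sd == pytest.approx(np.std(s.null_values, ddof=1))
        assert s.z == pytest.approx((part.q - s.mean) / s.sd)

    def test_degenerate_null_reports_z_none(self):
        g = nx.path_graph(["a", "b", "c"])  # rewiring can never change it
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = local_null(g, 0.5, iterations=3, seed=0)
        assert s.sd == 0.0 and s.z is None

    def test_reproducible_per_seed(self, bridged_cliques):
        part = girvan_newman(bridged_cliques)
        a = local_null(bridged_cliques, part.q, iterations=8, seed=13)
        b = local_null(bridged_cliques, part.q, iterations=8, seed=13)
        assert a.null_values == b.null_values
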