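"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import networkx as nx
import pytest

from altnet import graph as gr


# ---------------------------------------------------------------------------
# independent oracles (kept free of the implementation paths they check)


def brute_force_modularity(g: nx.Graph, assignment: dict[str, int]) -> float:
    """Q via the explicit pairwise form: (1/2L) sum_ij (A_ij - d_i d_j / 2L) delta."""
    L = g.number_of_edges()
    two_l = 2 * L
    total = 0.0
    nodes = list(g.nodes)
    for i in nodes:
        for j in nodes:
            if assignment[i] != assignment[j]:
                continue
            a_ij = 1.0 if g.has_edge(i, j) else 0.0
            total += a_ij - g.degree[i] * g.degree[j] / two_l
    return total / two_l


def set_partitions(items: list):
    """All set partitions of ``items`` (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [part[i] + [first]] + part[i + 1 :]
        yield part + [[first]]


def exhaustive_max_modularity(g: nx.Graph) -> float:
    """Maximal Q over every set partition of the nodes (brute force)."""
    best = float("-inf")
    L = g.number_of_edges()
    deg = dict(g.degree)
    edges = list(g.edges)
    for part in set_partitions(list(g.nodes)):
        label = {n: i for i, blk in enumerate(part) for n in blk}
        q = 0.0
        l_s: dict[int, int] = {}
        d_s: dict[int, int] = {}
        for n, s in label.items():
            d_s[s] = d_s.get(s, 0) + deg[n]
        for u, v in edges:
            if label[u] == label[v]:
                l_s[label[u]] = l_s.get(label[u], 0) + 1
        for s in d_s:
            q += l_s.get(s, 0) / L - (d_s[s] / (2 * L)) ** 2
        best = max(best, q)
    return best


def hypergeom_upper_tail(n: int, k: int, N: int, K: int) -> float:
    """P(X >= k) by direct combinatorial summation (self-free urn of N-1)."""
    from math import comb

    pop, succ = N - 1, K
    denom = comb(pop, n)
    num = sum(
        comb(succ, j) * comb(pop - succ, n - j)
        for j in range(k, min(n, succ) + 1)
        if pop - succ >= n - j
    )
    return num / denom


def bh_stepup_by_hand(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up applied literally to sorted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adj[i] = running
    return adj


# ---------------------------------------------------------------------------
# graph fixtures


@pytest.fixture
def triangle() -> nx.Graph:
    g = gr.new_network()
    for a, b in [("A", "B"), ("B", "C"), ("A", "C")]:
        gr.add_edge(g, a, b, ("pp", "test"))
    return g


@pytest.fixture
def two_triangles() -> nx.Graph:
    g = gr.new_network()
    for a, b in [("A", "B"), ("B", "C"), ("A", "C"), ("D", "E"), ("E", "F"), ("D", "F")]:
        gr.add_edge(g, a, b)
    return g


@pytest.fixture
def bridged_cliques() -> nx.Graph:
    """Two 4-cliques joined by a single bridge edge."""
    g = gr.new_network()
    left = ["A", "B", "C", "D"]
    right = ["E", "F", "G", "H"]
    for grp in (left, right):
        for i in range(4):
            for j in range(i + 1, 4):
                gr.add_edge(g, grp[i], grp[j])
    gr.add_edge(g, "D", "E")
    return g


def random_simple_graph(rng, n_max: int = 12, connected: bool = False) -> nx.Graph:
    """Seeded random graph with at least one edge, optionally connected."""
    while True:
        n = rng.randint(3, n_max)
        p = rng.uniform(0.2, 0.7)
        g = nx.gnp_random_graph(n, p, seed=rng.randint(0, 2**31 - 1))
        if g.number_of_edges() == 0:
            continue
        if connected and not nx.is_connected(g):
            continue
        return nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
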