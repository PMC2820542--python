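"""Module detection by edge-betweenness removal with max-modularity stopping.

Newman's modularity for a partition of a graph with L edges is

    Q = sum_s [ l_s / L  -  (d_s / 2L)^2 ]

where, for each module s, l_s is the number of edges with both endpoints in
s and d_s is the summed degree of its nodes.  Q ~ 0 when within-module edge
counts are no better than degree-matched chance; values toward 1 indicate
strong modular structure.

The Girvan-Newman procedure removes, one at a time, the edge carrying the
highest shortest-path betweenness (recomputing betweenness after every
removal), scoring the connected-component partition of the pruned graph
against the *original* graph's edges and degrees at each step, and returns
the partition of maximal Q over the whole removal sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

#: betweenness values closer than this are treated as tied
_TIE_EPS = 1e-9


@dataclass
class ModulePartition:
    """A node -> module-index assignment with its modularity bookkeeping.

    Module indices are assigned by decreasing module size, ties broken by
    the lexicographically smallest member.
    """

    assignment: dict[str, int]
    q: float
    n_modules: int
    l_s: list[int]  # within-module edge counts, by module index
    d_s: list[int]  # per-module degree sums over the reference network
    total_edges: int
    edges_removed: int = 0

    def members(self, module: int) -> list[str]:
        return sorted(n for n, m in self.assignment.items() if m == module)

    def summary(self) -> pd.DataFrame:
        rows = []
        for s in range(self.n_modules):
            size = sum(1 for m in self.assignment.values() if m == s)
            density = (
                2 * self.l_s[s] / (size * (size - 1)) if size > 1 else 0.0
            )
            rows.append((s, size, self.l_s[s], self.d_s[s], density))
        return pd.DataFrame(
            rows, columns=["module", "size", "within_edges", "degree_sum", "density"]
        )


def modularity(reference: nx.Graph, assignment: dict[str, int]) -> float:
    """Evaluate Q for ``assignment`` on ``reference``'s edges and degrees."""
    missing = set(reference.nodes) - set(assignment)
    if missing:
        raise ValueError(f"assignment misses {len(missing)} reference nodes")
    L = reference.number_of_edges()
    if L == 0:
        raise ValueError("modularity is undefined on an edgeless graph")
    l_s: dict[int, int] = {}
    d_s: dict[int, int] = {}
    for node in reference.nodes:
        s = assignment[node]
        d_s[s] = d_s.get(s, 0) + reference.degree[node]
    for u, v in reference.edges:
        if assignment[u] == assignment[v]:
            s = assignment[u]
            l_s[s] = l_s.get(s, 0) + 1
    return sum(
        l_s.get(s, 0) / L - (d_s[s] / (2 * L)) ** 2 for s in d_s
    )


def _canonical_assignment(components: list[set[str]]) -> dict[str, int]:
    ordered = sorted(components, key=lambda c: (-len(c), min(c)))
    return {n: i for i, comp in enumerate(ordered) for n in comp}


def _partition_from(reference: nx.Graph, pruned: nx.Graph, removed: int) -> ModulePartition:
    comps = [set(c) for c in nx.connected_components(pruned)]
    assignment = _canonical_assignment(comps)
    L = reference.number_of_edges()
    n_modules = len(comps)
    l_s = [0] * n_modules
    d_s = [0] * n_modules
    for node in reference.nodes:
        d_s[assignment[node]] += reference.degree[node]
    for u, v in reference.edges:
        if assignment[u] == assignment[v]:
            l_s[assignment[u]] += 1
    q = sum(l_s[s] / L - (d_s[s] / (2 * L)) ** 2 for s in range(n_modules))
    return ModulePartition(
        assignment=assignment,
        q=q,
        n_modules=n_modules,
        l_s=l_s,
        d_s=d_s,
        total_edges=L,
        edges_removed=removed,
    )


def girvan_newman(net: nx.Graph) -> ModulePartition:
    """Run the full removal sequence and return the max-Q partition.

    Determinism: among edges tied for maximal betweenness the
    lexicographically smallest sorted endpoint pair is removed; among
    removal counts tied for maximal Q the earliest (coarsest partition)
    wins.
    """
    if net.number_of_edges() == 0:
        raise ValueError("module detection requires at least one edge")
    work = nx.Graph()
    work.add_nodes_from(net.nodes)
    work.add_edges_from(net.edges)

    best = _partition_from(net, work, removed=0)
    removed = 0
    while work.number_of_edges() > 0:
        ebc = nx.edge_betweenness_centrality(work, normalized=False)
        top = max(ebc.values())
        tied = [tuple(sorted(e)) for e, v in ebc.items() if v >= top - _TIE_EPS]
        u, v = min(tied)
        work.remove_edge(u, v)
        removed += 1
        cand = _partition_from(net, work, removed=removed)
        if cand.q > best.q + 1e-12:
            best = cand
    return best
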