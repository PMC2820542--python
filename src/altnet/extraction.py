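"""Altered-gene subnetwork extraction with statistical linker selection.

Starting from an empty graph, every interaction between two altered genes
is copied in from the global network.  With a shortest-path threshold of 2,
non-altered neighbors of altered genes become *linker* candidates: a
candidate adjacent to exactly one altered gene connects nothing and is
pruned immediately, while each remaining candidate is scored with an
upper-tail hypergeometric test — given its global degree, how surprising
is its number of altered neighbors?  After Benjamini-Hochberg adjustment
across all candidates, linkers with q below the FDR cutoff are retained
together with their edges to altered genes and any global-network edges
among the retained linkers themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from . import graph as gr

ROLE_ALTERED = "ALTERED"
ROLE_LINKER = "LINKER"


@dataclass(frozen=True)
class LinkerCandidate:
    gene: str
    global_degree: int
    altered_neighbor_count: int
    p_value: float
    q_value: float


@dataclass
class ExtractedNetwork:
    graph: nx.Graph
    roles: dict[str, str]
    linker_stats: list[LinkerCandidate]
    candidates: list[LinkerCandidate] = field(default_factory=list)
    unplaced: list[str] = field(default_factory=list)
    sp_threshold: int = 2
    fdr_cutoff: float = 0.05


def linker_pvalue(
    global_degree: int, altered_neighbors: int, hin_size: int, altered_in_hin: int
) -> float:
    """Upper-tail hypergeometric probability for a linker candidate.

    P(X >= altered_neighbors) where X counts altered genes among
    ``global_degree`` draws without replacement from the ``hin_size - 1``
    other genes in the global network, of which ``altered_in_hin`` are
    altered.  The candidate is excluded from its own population (the
    self-free urn).
    """
    if not (0 <= altered_neighbors <= global_degree <= hin_size - 1):
        raise ValueError(
            f"need 0 <= k={altered_neighbors} <= n={global_degree} <= N-1={hin_size - 1}"
        )
    if not (0 <= altered_in_hin <= hin_size - 1):
        raise ValueError(f"altered_in_hin={altered_in_hin} outside [0, {hin_size - 1}]")
    # sf(k-1) = P(X >= k); hypergeom(M=population, n=successes, N=draws)
    return float(hypergeom.sf(altered_neighbors - 1, hin_size - 1, altered_in_hin, global_degree))


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    if any(not (0.0 <= p <= 1.0) for p in p_values):
        raise ValueError("p-values must lie in [0, 1]")
    if not p_values:
        return []
    return list(multipletests(p_values, method="fdr_bh")[1])


def extract_network(
    hin: nx.Graph,
    altered_genes: set[str],
    sp_threshold: int = 2,
    fdr_cutoff: float = 0.05,
) -> ExtractedNetwork:
    """Build the altered-gene subnetwork with enriched linkers.

    Parameters
    ----------
    hin
        Global interaction network (simple graph).
    altered_genes
        Genes passing the recurrence filter; silently restricted to genes
        present in ``hin``.
    sp_threshold
        1 keeps only direct altered-altered interactions; 2 additionally
        tests length-2 paths through linker candidates.
    fdr_cutoff
        Retain a linker when its BH-adjusted p-value is strictly below
        this cutoff.

    Altered genes left without a single retained edge are reported in
    ``unplaced`` rather than as isolated nodes.
    """
    if sp_threshold not in (1, 2):
        raise ValueError("sp_threshold must be 1 or 2")
    if not (0.0 < fdr_cutoff <= 1.0):
        raise ValueError("fdr_cutoff must be in (0, 1]")

    altered = sorted(set(altered_genes) & set(hin.nodes))
    g = gr.new_network()
    for a in altered:
        for b in hin.neighbors(a):
            if b in altered_genes and a < b:
                gr.add_edge(g, a, b)
                g.edges[a, b][gr.ANNOT] = set(hin.edges[a, b].get(gr.ANNOT, ()))

    candidates: list[LinkerCandidate] = []
    retained: list[LinkerCandidate] = []
    if sp_threshold == 2 and altered:
        altered_set = set(altered)
        neighbor_counts: dict[str, int] = {}
        for a in altered:
            for y in hin.neighbors(a):
                if y not in altered_set:
                    neighbor_counts[y] = neighbor_counts.get(y, 0) + 1
        # degree-1 neighbors connect nothing: pruned before testing
        tested = sorted(y for y, k in neighbor_counts.items() if k >= 2)
        if tested:
            n_hin = hin.number_of_nodes()
            pvals = [
                linker_pvalue(hin.degree[y], neighbor_counts[y], n_hin, len(altered))
                for y in tested
            ]
            qvals = bh_adjust(pvals)
            for y, p, q in zip(tested, pvals, qvals):
                cand = LinkerCandidate(y, hin.degree[y], neighbor_counts[y], p, q)
                candidates.append(cand)
                if q < fdr_cutoff:
                    retained.append(cand)
            for cand in retained:
                for a in hin.neighbors(cand.gene):
                    if a in altered_set:
                        gr.add_edge(g, cand.gene, a)
                        g.edges[cand.gene, a][gr.ANNOT] = set(
                            hin.edges[cand.gene, a].get(gr.ANNOT, ())
                        )
            linker_set = {c.gene for c in retained}
            for u in sorted(linker_set):
                for v in hin.neighbors(u):
                    if v in linker_set and u < v:
                        gr.add_edge(g, u, v)
                        g.edges[u, v][gr.ANNOT] = set(hin.edges[u, v].get(gr.ANNOT, ()))

    linker_set = {c.gene for c in retained}
    roles = {
        n: (ROLE_LINKER if n in linker_set else ROLE_ALTERED) for n in g.nodes
    }
    unplaced = [a for a in altered if a not in g]
    return ExtractedNetwork(
        graph=g,
        roles=roles,
        linker_stats=retained,
        candidates=candidates,
        unplaced=unplaced,
        sp_threshold=sp_threshold,
        fdr_cutoff=fdr_cutoff,
    )
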