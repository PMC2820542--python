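"""Interaction-network data model and I/O.

The global interaction network and every graph derived from it is an
undirected *simple* graph over gene symbols: no self-edges, no parallel
edges.  Redundant records for the same gene pair (e.g. the same physical
interaction curated by two sources, or a directed annotation recorded in
both directions) are collapsed into a single edge whose ``annotations``
attribute accumulates ``(interaction_type, data_source)`` tags.

Gene identity is the verbatim token from the input file; no symbol or
identifier mapping is performed, so all inputs to one analysis must share a
namespace.
"""

from __future__ import annotations

import os
from typing import Iterable

import networkx as nx

__all__ = [
    "load_network",
    "degree",
    "largest_component",
    "add_edge",
    "new_network",
    "write_sif",
    "write_edge_attributes",
]

#: edge attribute holding the set of (interaction_type, data_source) tags
ANNOT = "annotations"


def new_network() -> nx.Graph:
    """Return an empty interaction network with collapse counters."""
    g = nx.Graph()
    g.graph["n_duplicates_collapsed"] = 0
    g.graph["n_self_edges_dropped"] = 0
    return g


def add_edge(net: nx.Graph, a: str, b: str, annotation: tuple[str, str] | None = None) -> None:
    """Add an undirected edge, enforcing the simple-graph contract.

    Self-edges are dropped (the node is still registered); a repeated pair
    only accumulates the annotation and bumps the duplicate counter.
    """
    _check_gene(a)
    _check_gene(b)
    if a == b:
        net.add_node(a)
        net.graph["n_self_edges_dropped"] = net.graph.get("n_self_edges_dropped", 0) + 1
        return
    if net.has_edge(a, b):
        net.graph["n_duplicates_collapsed"] = net.graph.get("n_duplicates_collapsed", 0) + 1
        if annotation is not None:
            net.edges[a, b][ANNOT].add(annotation)
    else:
        net.add_edge(a, b)
        net.edges[a, b][ANNOT] = {annotation} if annotation is not None else set()


def _check_gene(symbol: str) -> None:
    if not symbol or any(c.isspace() for c in symbol):
        raise ValueError(f"invalid gene symbol: {symbol!r}")


def load_network(path: str, dialect: str = "sif3", source: str | None = None) -> nx.Graph:
    """Load a tab-delimited edge list as a collapsed simple graph.

    Parameters
    ----------
    path
        File with one interaction per line.  ``sif3`` lines are
        ``geneA<TAB>type<TAB>geneB``; ``edge2`` lines are
        ``geneA<TAB>geneB``.  Lines starting with ``#`` and blank lines are
        skipped.
    dialect
        ``"sif3"`` or ``"edge2"``.
    source
        Data-source tag recorded on every annotation; defaults to the file
        basename.

    Returns
    -------
    networkx.Graph
        Simple graph; ``graph["n_duplicates_collapsed"]`` and
        ``graph["n_self_edges_dropped"]`` report what the collapse removed.
    """
    if dialect not in ("sif3", "edge2"):
        raise ValueError(f"unknown dialect: {dialect!r}")
    if source is None:
        source = os.path.basename(path)
    net = new_network()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                # SIF allows a lone node name for an isolated node
                try:
                    _check_gene(fields[0].strip())
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
                net.add_node(fields[0].strip())
                continue
            if dialect == "sif3":
                if len(fields) != 3:
                    raise ValueError(
                        f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}"
                    )
                a, itype, b = fields
            else:
                if len(fields) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
                    )
                a, b = fields
                itype = "pp"
            try:
                add_edge(net, a.strip(), b.strip(), (itype.strip(), source))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return net


def degree(net: nx.Graph, gene: str) -> int:
    """Number of distinct neighbors of ``gene`` (after edge collapse)."""
    if gene not in net:
        raise KeyError(f"gene not in network: {gene!r}")
    return net.degree[gene]


def largest_component(net: nx.Graph) -> tuple[int, int, frozenset[str]]:
    """Largest connected component as (node_count, edge_count, members).

    Ties on node count break on larger edge count, then on the
    lexicographically smallest sorted member list.  The empty network
    yields ``(0, 0, frozenset())``.
    """
    if net.number_of_nodes() == 0:
        return (0, 0, frozenset())
    best = None
    for comp in nx.connected_components(net):
        n = len(comp)
        e = net.subgraph(comp).number_of_edges()
        key = (-n, -e, sorted(comp))
        if best is None or key < best[0]:
            best = (key, (n, e, frozenset(comp)))
    return best[1]


def write_sif(net: nx.Graph, path: str) -> None:
    """Write the network in Cytoscape SIF format, one line per edge and
    interaction type, in sorted order.  Edges with no annotation are tagged
    ``pp``; isolated nodes are emitted as single-column lines."""
    lines = []
    for u, v, data in net.edges(data=True):
        a, b = sorted((u, v))
        types = sorted({t for t, _src in data.get(ANNOT, ())}) or ["pp"]
        for t in types:
            lines.append(f"{a}\t{t}\t{b}")
    for node in net.nodes:
        if net.degree[node] == 0:
            lines.append(node)
    with open(path, "wt", encoding="utf-8") as fh:
        for line in sorted(lines):
            fh.write(line + "\n")


def write_edge_attributes(net: nx.Graph, path: str, name: str = "data_source") -> None:
    """Write a Cytoscape edge-attribute file (``A (pp) B = src1;src2``)."""
    lines = []
    for u, v, data in net.edges(data=True):
        a, b = sorted((u, v))
        ann = data.get(ANNOT, set())
        types = sorted({t for t, _ in ann}) or ["pp"]
        sources = sorted({s for _, s in ann})
        for t in types:
            lines.append(f"{a} ({t}) {b} = {';'.join(sources) if sources else 'NA'}")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(name + "\n")
        for line in sorted(lines):
            fh.write(line + "\n")


def node_union(graphs: Iterable[nx.Graph]) -> set[str]:
    """Union of node sets across graphs."""
    out: set[str] = set()
    for g in graphs:
        out |= set(g.nodes)
    return out
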