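"""Permutation null models for network connectivity and modularity.

Two complementary nulls quantify how surprising the extracted network is:

*Global random-gene-set null.*  Re-run the full extraction on gene sets of
the same size drawn uniformly from the global network, and compare the
largest connected component (nodes and edges) of each random run to the
observed one.  The empirical p-value is the fraction of iterations whose
largest component equals or exceeds the observed.

*Local degree-preserving rewiring null.*  Randomize the extracted network
itself by Maslov-Sneppen double-edge swaps (every node keeps its exact
degree; partners are random), re-run module detection on each rewired
graph, and convert the observed maximal modularity into a z-score — the
*scaled modularity* — against the null mean and sample standard deviation.

Iteration-level random streams are derived from the master seed by a
counter-based scheme, so results are independent of execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .extraction import extract_network
from .graph import largest_component
from .modules import girvan_newman

GLOBAL_GENE_SET = "GLOBAL_GENE_SET"
LOCAL_REWIRE = "LOCAL_REWIRE"


@dataclass
class NullSummary:
    kind: str
    iterations: int
    seed: int
    observed: tuple[int, int] | float
    null_values: list = field(default_factory=list)
    mean: float = float("nan")
    sd: float = float("nan")
    p_nodes: float | None = None
    p_edges: float | None = None
    z: float | None = None

    def format_p(self, p: float) -> str:
        """Zero exceedances are reported as a bound, not as p = 0."""
        return f"< {1 / self.iterations:g}" if p == 0.0 else f"{p:g}"


def _iter_rng(seed: int, iteration: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(iteration,)))


def scaled_modularity(q_observed: float, null_mean: float, null_sd: float) -> float:
    """z-score of the observed modularity against a null distribution."""
    if null_sd <= 0:
        raise ValueError("scaled modularity is undefined when the null sd is 0")
    return (q_observed - null_mean) / null_sd


def global_null(
    hin: nx.Graph,
    n_genes: int,
    observed: tuple[int, int],
    sp_threshold: int = 2,
    fdr_cutoff: float = 0.05,
    iterations: int = 1000,
    seed: int = 0,
) -> NullSummary:
    """Random-gene-set connectivity null.

    Per iteration, ``n_genes`` genes are sampled without replacement from
    the global network and extracted with the same shortest-path threshold
    and FDR cutoff; the largest component's node and edge counts are
    recorded.  ``p_nodes``/``p_edges`` are the fractions of iterations
    meeting or exceeding the observed counts.
    """
    nodes = sorted(hin.nodes)
    if n_genes > len(nodes):
        raise ValueError(f"cannot sample {n_genes} genes from {len(nodes)} network genes")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    obs_nodes, obs_edges = observed
    draws: list[tuple[int, int]] = []
    for i in range(iterations):
        rng = _iter_rng(seed, i)
        sample = set(rng.choice(nodes, size=n_genes, replace=False))
        ext = extract_network(hin, sample, sp_threshold=sp_threshold, fdr_cutoff=fdr_cutoff)
        n, e, _members = largest_component(ext.graph)
        draws.append((n, e))
    node_counts = np.array([d[0] for d in draws])
    edge_counts = np.array([d[1] for d in draws])
    return NullSummary(
        kind=GLOBAL_GENE_SET,
        iterations=iterations,
        seed=seed,
        observed=observed,
        null_values=draws,
        mean=float(node_counts.mean()),
        sd=float(node_counts.std(ddof=1)) if iterations > 1 else 0.0,
        p_nodes=float((node_counts >= obs_nodes).mean()),
        p_edges=float((edge_counts >= obs_edges).mean()),
    )


def rewire(
    net: nx.Graph, swap_multiplier: int = 10, seed: int = 0
) -> nx.Graph:
    """Degree-preserving randomization by double-edge swaps.

    Attempts ``swap_multiplier * |E|`` successful swaps: two distinct edges
    (a, b) and (c, d) are picked uniformly and replaced by (a, d) and
    (c, b); swaps creating self-edges or parallel edges are rejected and
    retried.  If no valid swap can be found within a bounded number of
    attempts (e.g. a star graph) the input topology is returned unchanged
    with a warning.
    """
    if net.number_of_edges() < 2:
        raise ValueError("rewiring requires at least 2 edges")
    rng = _iter_rng(seed, 0) if isinstance(seed, int) else seed
    edges = [tuple(sorted(e)) for e in net.edges]
    edges.sort()
    edge_set = set(edges)
    target = swap_multiplier * len(edges)
    max_attempts = 200 * target
    swaps = attempts = 0
    while swaps < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.choice(len(edges), size=2, replace=False)
        a, b = edges[i]
        c, d = edges[j]
        if rng.random() < 0.5:
            c, d = d, c
        # proposed replacement: (a, d) and (c, b)
        if a == d or c == b:
            continue
        e1, e2 = tuple(sorted((a, d))), tuple(sorted((c, b)))
        if e1 == e2 or e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edges[i])
        edge_set.discard(edges[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edges[i], edges[j] = e1, e2
        swaps += 1
    if swaps < target:
        warnings.warn(
            f"rewire reached {swaps}/{target} swaps after {attempts} attempts; "
            "graph admits few or no valid swaps",
            stacklevel=2,
        )
    out = nx.Graph()
    out.add_nodes_from(net.nodes)
    out.add_edges_from(edge_set)
    return out


def local_null(
    net: nx.Graph,
    q_observed: float,
    iterations: int = 1000,
    swap_multiplier: int = 10,
    seed: int = 0,
) -> NullSummary:
    """Rewiring null for modularity; yields the scaled modularity z.

    Per iteration the network is rewired and module detection re-run in
    full; z = (Q_observed - mean) / sd over the null Q values (sample sd,
    n-1).  A degenerate null (sd = 0) leaves z as None.
    """
    if iterations < 2:
        raise ValueError("local null needs >= 2 iterations for a sample sd")
    qs: list[float] = []
    for i in range(iterations):
        rng = _iter_rng(seed, i + 1)
        rewired = rewire(net, swap_multiplier=swap_multiplier, seed=rng)
        qs.append(girvan_newman(rewired).q)
    arr = np.array(qs)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    z = scaled_modularity(q_observed, mean, sd) if sd > 0 else None
    return NullSummary(
        kind=LOCAL_REWIRE,
        iterations=iterations,
        seed=seed,
        observed=q_observed,
        null_values=qs,
        mean=mean,
        sd=sd,
        z=z,
    )
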