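"""Synthetic interaction networks and alteration matrices.

Real runs of this pipeline need a curated interaction network and tumor
alteration calls; these generators produce structurally analogous inputs at
desk scale so every stage is testable end to end.  The planted-partition
generator embeds a few dense gene modules into a sparse background graph
and marks their members as the recurrently altered genes — emulating the
working hypothesis that tumors concentrate alterations in a small number
of tightly connected processes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from . import graph as gr
from .alterations import AlterationMatrix

ALTERED_STATE_CHOICES = ("MUTATION", "HOMOZYGOUS_DELETION", "AMPLIFICATION")


@dataclass
class PlantedTruth:
    """Ground truth for a planted-module benchmark instance."""

    module_assignments: dict[str, int]
    altered_genes: set[str]
    all_genes: list[str]
    parameters: dict = field(default_factory=dict)


def _gene_label(i: int) -> str:
    return f"G{i:05d}"


def synth_hin(
    n_genes: int, mean_degree: float, model: str = "ER", seed: int = 0
) -> nx.Graph:
    """Random background interaction network.

    ``model="ER"`` draws an Erdos-Renyi graph with edge probability
    ``mean_degree / (n_genes - 1)``; ``model="BA"`` grows a
    preferential-attachment graph with ``round(mean_degree / 2)`` edges per
    new node (heavier-tailed degrees, closer to curated interactomes).
    """
    if n_genes < 3:
        raise ValueError("n_genes must be >= 3")
    if not (0 < mean_degree <= n_genes - 1):
        raise ValueError("mean_degree must lie in (0, n_genes - 1]")
    if model == "ER":
        g = nx.gnp_random_graph(n_genes, mean_degree / (n_genes - 1), seed=seed)
    elif model == "BA":
        m = max(1, round(mean_degree / 2))
        g = nx.barabasi_albert_graph(n_genes, m, seed=seed)
    else:
        raise ValueError(f"unknown model {model!r}")
    mapping = {i: _gene_label(i) for i in g.nodes}
    net = gr.new_network()
    net.add_nodes_from(mapping.values())
    for u, v in g.edges:
        gr.add_edge(net, mapping[u], mapping[v], ("pp", "synthetic"))
    return net


def plant_modules(
    hin: nx.Graph,
    n_modules: int,
    module_size: int,
    p_within: float,
    p_between: float,
    seed: int = 0,
) -> tuple[nx.Graph, PlantedTruth]:
    """Embed dense altered-gene modules into a background network.

    Disjoint gene sets are chosen at random; each within-module gene pair
    is made an edge with probability ``p_within`` and each pair spanning
    two planted modules with probability ``p_between`` (existing edges at
    those pairs are resampled; edges to background genes are untouched).
    All planted genes are marked altered in the returned truth.
    """
    if not (0 <= p_between < p_within <= 1):
        raise ValueError("need 0 <= p_between < p_within <= 1")
    if n_modules * module_size > hin.number_of_nodes():
        raise ValueError("not enough genes to plant the requested modules")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    nodes = sorted(hin.nodes)
    chosen = rng.choice(nodes, size=n_modules * module_size, replace=False)
    assignment = {
        g: i for i, block in enumerate(np.split(chosen, n_modules)) for g in block
    }
    net = hin.copy()
    planted = sorted(assignment)
    for a, b in combinations(planted, 2):
        p = p_within if assignment[a] == assignment[b] else p_between
        want = rng.random() < p
        if want and not net.has_edge(a, b):
            gr.add_edge(net, a, b, ("pp", "planted"))
        elif not want and net.has_edge(a, b):
            net.remove_edge(a, b)
    truth = PlantedTruth(
        module_assignments=assignment,
        altered_genes=set(planted),
        all_genes=nodes,
        parameters={
            "n_genes": hin.number_of_nodes(),
            "n_modules": n_modules,
            "module_size": module_size,
            "p_within": p_within,
            "p_between": p_between,
            "seed": seed,
        },
    )
    return net, truth


def synth_alterations(
    truth: PlantedTruth,
    n_cases: int = 84,
    per_gene_rate: float = 0.15,
    background_rate: float = 0.003,
    hypermutator_fraction: float = 0.0,
    seed: int = 0,
) -> AlterationMatrix:
    """Simulate per-case alteration calls for a planted benchmark.

    Each planted gene is altered in each case with ``per_gene_rate``
    (recurrent drivers); background genes with ``background_rate``
    (sporadic passengers).  Cases flagged as hypermutators have both rates
    multiplied by 10 (capped at 1).  States are drawn uniformly from
    mutation / homozygous deletion / amplification.

    Defaults mirror a cohort of 84 retained cases where driver genes are
    altered in a double-digit percentage of cases while only a small
    percentage of background genes reach the 2-case recurrence threshold.
    """
    for name, r in (("per_gene_rate", per_gene_rate), ("background_rate", background_rate),
                    ("hypermutator_fraction", hypermutator_fraction)):
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    cases = [f"case{i:03d}" for i in range(n_cases)]
    n_hyper = int(round(hypermutator_fraction * n_cases))
    hyper = set(rng.choice(cases, size=n_hyper, replace=False)) if n_hyper else set()
    m = AlterationMatrix(cases=list(cases), hypermutators=hyper)
    planted = truth.altered_genes
    for case in cases:
        boost = 10.0 if case in hyper else 1.0
        for gene in truth.all_genes:
            rate = per_gene_rate if gene in planted else background_rate
            if rng.random() < min(1.0, rate * boost):
                state = ALTERED_STATE_CHOICES[rng.integers(len(ALTERED_STATE_CHOICES))]
                m.states[(case, gene)] = state
    return m


def write_fixture_dir(
    outdir: str,
    n_genes: int = 250,
    mean_degree: float = 8.0,
    model: str = "ER",
    n_modules: int = 3,
    module_size: int = 6,
    p_within: float = 0.9,
    p_between: float = 0.05,
    n_cases: int = 84,
    per_gene_rate: float = 0.15,
    background_rate: float = 0.003,
    hypermutator_fraction: float = 0.0,
    seed: int = 0,
) -> dict[str, str]:
    """Emit a ready-to-run fixture directory (SIF, alteration TSV, truth).

    Returns a name -> path manifest of the written files.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    hin = synth_hin(n_genes, mean_degree, model=model, seed=seed)
    hin, truth = plant_modules(hin, n_modules, module_size, p_within, p_between, seed=seed)
    matrix = synth_alterations(
        truth,
        n_cases=n_cases,
        per_gene_rate=per_gene_rate,
        background_rate=background_rate,
        hypermutator_fraction=hypermutator_fraction,
        seed=seed,
    )
    paths = {
        "network": os.path.join(outdir, "network.sif"),
        "alterations": os.path.join(outdir, "alterations.tsv"),
        "hypermutators": os.path.join(outdir, "hypermutators.txt"),
        "truth": os.path.join(outdir, "truth.json"),
    }
    gr.write_sif(hin, paths["network"])
    with open(paths["alterations"], "wt", encoding="utf-8") as fh:
        for (case, gene) in sorted(matrix.states):
            fh.write(f"{case}\t{gene}\t{matrix.states[(case, gene)]}\n")
        # explicit NONE rows keep alteration-free cases in the cohort
        recorded = {c for (c, _g) in matrix.states}
        for case in matrix.cases:
            if case not in recorded:
                fh.write(f"{case}\t{truth.all_genes[0]}\tNONE\n")
    with open(paths["hypermutators"], "wt", encoding="utf-8") as fh:
        for case in sorted(matrix.hypermutators):
            fh.write(case + "\n")
    with open(paths["truth"], "wt", encoding="utf-8") as fh:
        json.dump(
            {
                "module_assignments": dict(sorted(truth.module_assignments.items())),
                "altered_genes": sorted(truth.altered_genes),
                "parameters": truth.parameters,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return paths
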