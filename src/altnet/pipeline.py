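"""End-to-end orchestration: alterations -> extraction -> modules -> nulls.

`run_pipeline` drives the whole analysis from a `RunConfig` (YAML file plus
overrides); `analyze` is the in-memory core reused by the null models, the
synthetic benchmarks, and the CLI.  `write_outputs` serializes everything
in Cytoscape-compatible form with fully sorted, timestamp-free content so
a fixed seed reproduces a byte-identical output directory.
"""

from __future__ import annotations

import logging
import os
import sys
from dataclasses import dataclass, field, asdict

import networkx as nx
import yaml

from . import __version__
from . import graph as gr
from .alterations import AlteredGeneSet, altered_gene_set, load_alterations, write_frequencies
from .extraction import ExtractedNetwork, extract_network
from .modules import ModulePartition, girvan_newman
from .nulls import NullSummary, global_null, local_null

log = logging.getLogger("altnet")


@dataclass
class RunConfig:
    network: str = ""
    alterations: str = ""
    hypermutators: str | None = None
    outdir: str = "altnet_out"
    min_cases: int = 2
    exclude_hypermutators: bool = True
    sp_threshold: int = 2
    linker_fdr: float = 0.05
    run_global_null: bool = True
    run_local_null: bool = True
    global_iterations: int = 1000
    local_iterations: int = 1000
    swap_multiplier: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.linker_fdr <= 1):
            raise ValueError("linker_fdr must be in (0, 1]")
        if self.sp_threshold not in (1, 2):
            raise ValueError("sp_threshold must be 1 or 2")
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")
        if self.global_iterations < 1 or self.local_iterations < 1:
            raise ValueError("iteration counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)


@dataclass
class RunResult:
    config: RunConfig
    altered: AlteredGeneSet
    extracted: ExtractedNetwork
    partition: ModulePartition | None
    global_summary: NullSummary | None
    local_summary: NullSummary | None
    largest: tuple[int, int, frozenset[str]]
    provenance: dict = field(default_factory=dict)


def analyze(
    hin: nx.Graph,
    altered: AlteredGeneSet,
    config: RunConfig,
) -> RunResult:
    """Run extraction, module detection and the requested nulls."""
    config.validate()
    log.info("altered genes passing threshold: %d", len(altered.genes))
    extracted = extract_network(
        hin, altered.genes, sp_threshold=config.sp_threshold, fdr_cutoff=config.linker_fdr
    )
    n_in_net = sum(1 for r in extracted.roles.values() if r == "ALTERED")
    log.info(
        "extracted network: %d altered + %d linker genes, %d edges (%d altered genes unplaced)",
        n_in_net,
        len(extracted.linker_stats),
        extracted.graph.number_of_edges(),
        len(extracted.unplaced),
    )
    largest = gr.largest_component(extracted.graph)

    partition = None
    local_summary = None
    if extracted.graph.number_of_edges() == 0:
        log.warning("extracted network has no edges; skipping module detection and nulls")
        global_summary = None
    else:
        partition = girvan_newman(extracted.graph)
        log.info("modules: %d, modularity Q = %.4f", partition.n_modules, partition.q)
        global_summary = None
        altered_in_hin = len(set(altered.genes) & set(hin.nodes))
        if config.run_global_null and altered_in_hin > 0:
            global_summary = global_null(
                hin,
                n_genes=altered_in_hin,
                observed=largest[:2],
                sp_threshold=config.sp_threshold,
                fdr_cutoff=config.linker_fdr,
                iterations=config.global_iterations,
                seed=config.seed,
            )
            log.info(
                "global null: p_nodes = %s, p_edges = %s",
                global_summary.format_p(global_summary.p_nodes),
                global_summary.format_p(global_summary.p_edges),
            )
        if config.run_local_null and extracted.graph.number_of_edges() >= 2:
            local_summary = local_null(
                extracted.graph,
                q_observed=partition.q,
                iterations=config.local_iterations,
                swap_multiplier=config.swap_multiplier,
                seed=config.seed,
            )
            log.info(
                "local null: mean Q = %.4f, sd = %.4f, scaled modularity z = %s",
                local_summary.mean,
                local_summary.sd,
                "NA" if local_summary.z is None else f"{local_summary.z:.2f}",
            )

    provenance = {
        "altnet_version": __version__,
        "python": sys.version.split()[0],
        "parameters": asdict(config),
        "seed": config.seed,
    }
    return RunResult(
        config=config,
        altered=altered,
        extracted=extracted,
        partition=partition,
        global_summary=global_summary,
        local_summary=local_summary,
        largest=largest,
        provenance=provenance,
    )


def run_pipeline(config: RunConfig) -> RunResult:
    """Load inputs per ``config`` and run the full analysis."""
    config.validate()
    hin = gr.load_network(config.network, dialect="sif3")
    log.info(
        "interaction network: %d genes, %d interactions",
        hin.number_of_nodes(),
        hin.number_of_edges(),
    )
    matrix = load_alterations(config.alterations, hypermutator_path=config.hypermutators)
    altered = altered_gene_set(
        matrix, min_cases=config.min_cases, exclude_hypermutators=config.exclude_hypermutators
    )
    return analyze(hin, altered, config)


# ---------------------------------------------------------------------------
# output writing


def _write_node_attr(path: str, name: str, values: dict[str, object]) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(name + "\n")
        for node in sorted(values):
            fh.write(f"{node} = {values[node]}\n")


def write_outputs(result: RunResult, outdir: str) -> list[str]:
    """Write the Cytoscape files, TSVs and reports; return the manifest."""
    os.makedirs(outdir, exist_ok=True)
    manifest: list[str] = []

    def reg(name: str) -> str:
        manifest.append(name)
        return os.path.join(outdir, name)

    gr.write_sif(result.extracted.graph, reg("network.sif"))
    gr.write_edge_attributes(result.extracted.graph, reg("edge_sources.ea"))

    _write_node_attr(reg("role.na"), "role", result.extracted.roles)
    freqs = {
        g: f"{result.altered.counts.get(g, 0) / result.altered.n_cases:.6f}"
        for g in result.extracted.roles
    }
    _write_node_attr(reg("alteration_frequency.na"), "alteration_frequency", freqs)
    qvals = {c.gene: f"{c.q_value:.6g}" for c in result.extracted.linker_stats}
    _write_node_attr(reg("linker_q.na"), "linker_q_value", qvals)
    if result.partition is not None:
        _write_node_attr(reg("module.na"), "module_index", result.partition.assignment)
        result.partition.summary().to_csv(
            reg("modules_summary.tsv"), sep="\t", index=False, float_format="%.6f"
        )

    write_frequencies(result.altered, reg("gene_frequencies.tsv"))

    with open(reg("linker_statistics.tsv"), "wt", encoding="utf-8") as fh:
        fh.write("gene\tglobal_degree\taltered_neighbors\tp_value\tq_value\tretained\n")
        kept = {c.gene for c in result.extracted.linker_stats}
        for c in sorted(result.extracted.candidates, key=lambda c: (c.q_value, c.gene)):
            fh.write(
                f"{c.gene}\t{c.global_degree}\t{c.altered_neighbor_count}\t"
                f"{c.p_value:.6g}\t{c.q_value:.6g}\t{c.gene in kept}\n"
            )

    for summary, name, stat in (
        (result.global_summary, "null_global.tsv", "nodes\tedges"),
        (result.local_summary, "null_local.tsv", "q"),
    ):
        if summary is None:
            continue
        with open(reg(name), "wt", encoding="utf-8") as fh:
            fh.write(f"iteration\t{stat}\n")
            for i, val in enumerate(summary.null_values):
                if isinstance(val, tuple):
                    fh.write(f"{i}\t{val[0]}\t{val[1]}\n")
                else:
                    fh.write(f"{i}\t{val:.6f}\n")

    report = _render_report(result)
    with open(reg("report.txt"), "wt", encoding="utf-8") as fh:
        fh.write(report)
    with open(reg("report.html"), "wt", encoding="utf-8") as fh:
        fh.write(
            "<!DOCTYPE html>\n<html><head><meta charset='utf-8'>"
            "<title>altnet report</title></head>\n"
            "<body><pre>\n{}</pre></body></html>\n".format(report)
        )

    manifest.append("MANIFEST.txt")
    with open(os.path.join(outdir, "MANIFEST.txt"), "wt", encoding="utf-8") as fh:
        for name in sorted(manifest):
            fh.write(name + "\n")
    return sorted(manifest)


def _render_report(result: RunResult) -> str:
    lines = []
    cfg = result.config
    lines.append("altnet run report")
    lines.append("=================")
    lines.append("")
    lines.append("parameters:")
    for k, v in sorted(asdict(cfg).items()):
        if k == "outdir":  # the only value that varies between re-runs
            continue
        lines.append(f"  {k}: {v}")
    lines.append("")
    lines.append(f"cases retained: {result.altered.n_cases}")
    lines.append(f"genes passing recurrence threshold: {len(result.altered.genes)}")
    n_alt = sum(1 for r in result.extracted.roles.values() if r == "ALTERED")
    lines.append(f"altered genes placed in network: {n_alt}")
    lines.append(f"linker genes retained: {len(result.extracted.linker_stats)}")
    lines.append(f"altered genes unplaced: {len(result.extracted.unplaced)}")
    n, e, _ = result.largest
    lines.append(f"largest component: {n} nodes, {e} edges")
    if result.partition is not None:
        lines.append(f"modules: {result.partition.n_modules}")
        lines.append(f"modularity Q: {result.partition.q:.4f}")
    if result.global_summary is not None:
        s = result.global_summary
        lines.append(
            f"global null ({s.iterations} iterations): "
            f"p_nodes = {s.format_p(s.p_nodes)}, p_edges = {s.format_p(s.p_edges)}"
        )
    if result.local_summary is not None:
        s = result.local_summary
        z = "NA (degenerate null)" if s.z is None else f"{s.z:.2f}"
        lines.append(
            f"local null ({s.iterations} iterations): mean Q = {s.mean:.4f}, "
            f"sd = {s.sd:.4f}, scaled modularity z = {z}"
        )
    lines.append("")
    lines.append(f"altnet version: {result.provenance['altnet_version']}")
    lines.append(f"seed: {result.provenance['seed']}")
    return "\n".join(lines) + "\n"
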