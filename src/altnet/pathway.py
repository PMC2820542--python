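"""Reduction of simplified biochemical pathway models to binary interactions.

Pathway databases describe biology as reactions with inputs, outputs and
controllers, and as molecular complexes — while module-detection algorithms
want a plain gene-gene graph.  This module implements the five reduction
rule families that bridge the two:

``IN_SAME_COMPLEX``
    every pair of distinct genes whose products sit in the same
    (recursively flattened) complex;
``REACTS_WITH``
    every pair of distinct genes among the *inputs* of one reaction;
``STATE_CHANGE``
    controller gene -> substrate gene, for a reaction that converts a
    molecule between two states of the same gene (e.g. a kinase
    phosphorylating its substrate);
``SEQUENTIAL_CATALYSIS``
    controllers of two reactions chained by a shared molecule (an output of
    the first is an input of the second, same molecule id);
``CO_CONTROL``
    every pair of distinct genes controlling the same reaction.

Molecules without a gene reference (small molecules, ATP and friends) never
generate edges, and pairs that collapse to a single gene (homodimers) are
suppressed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from . import graph as gr

RULE_TAGS = (
    "IN_SAME_COMPLEX",
    "REACTS_WITH",
    "STATE_CHANGE",
    "SEQUENTIAL_CATALYSIS",
    "CO_CONTROL",
)


@dataclass(frozen=True)
class BinaryInteraction:
    a: str
    b: str
    rule_tag: str


@dataclass
class PathwayModel:
    """A minimal reaction-table pathway model.

    molecules: molecule id -> (gene_ref or None, state label)
    complexes: complex id -> member ids (molecule or complex ids)
    reactions: reaction id -> (input molecule ids, output molecule ids)
    controls:  (controller molecule id, reaction id, control type)
    """

    molecules: dict[str, tuple[str | None, str]] = field(default_factory=dict)
    complexes: dict[str, list[str]] = field(default_factory=dict)
    reactions: dict[str, tuple[list[str], list[str]]] = field(default_factory=dict)
    controls: list[tuple[str, str, str]] = field(default_factory=list)

    def validate(self) -> None:
        """Raise ValueError listing every dangling reference or cycle."""
        bad: list[str] = []
        defined = set(self.molecules) | set(self.complexes)
        for cid, members in self.complexes.items():
            for m in members:
                if m not in defined:
                    bad.append(f"complex {cid} -> {m}")
        for rid, (ins, outs) in self.reactions.items():
            for m in ins + outs:
                if m not in defined:
                    bad.append(f"reaction {rid} -> {m}")
        for ctrl, rid, _ctype in self.controls:
            if ctrl not in defined:
                bad.append(f"control -> {ctrl}")
            if rid not in self.reactions:
                bad.append(f"control -> {rid}")
        if bad:
            raise ValueError("dangling references: " + "; ".join(sorted(bad)))
        # complex membership must be acyclic
        seen_stack: set[str] = set()
        done: set[str] = set()

        def walk(cid: str) -> None:
            if cid in done:
                return
            if cid in seen_stack:
                raise ValueError(f"complex membership cycle at {cid}")
            seen_stack.add(cid)
            for m in self.complexes.get(cid, ()):
                if m in self.complexes:
                    walk(m)
            seen_stack.discard(cid)
            done.add(cid)

        for cid in self.complexes:
            walk(cid)

    # -- helpers -----------------------------------------------------------

    def gene_of(self, molecule_id: str) -> str | None:
        entry = self.molecules.get(molecule_id)
        return entry[0] if entry else None

    def flatten_complex(self, cid: str) -> list[str]:
        """Molecule ids reachable from a complex, sub-complexes flattened."""
        out: list[str] = []
        for m in self.complexes[cid]:
            if m in self.complexes:
                out.extend(self.flatten_complex(m))
            else:
                out.append(m)
        return out

    def controllers_of(self, rid: str) -> list[str]:
        return [ctrl for ctrl, r, _t in self.controls if r == rid]


def _pairs(genes: list[str], tag: str) -> list[BinaryInteraction]:
    uniq = sorted(set(g for g in genes if g is not None))
    return [BinaryInteraction(a, b, tag) for a, b in combinations(uniq, 2)]


def reduce_pathway(model: PathwayModel, rules: set[str] | None = None) -> list[BinaryInteraction]:
    """Apply the enabled reduction rules and return the emitted interactions.

    ``rules`` defaults to all five rule families.  Output order is
    deterministic (rule tag, then sorted gene pair).
    """
    if rules is None:
        rules = set(RULE_TAGS)
    unknown = rules - set(RULE_TAGS)
    if unknown:
        raise ValueError(f"unknown rule tags: {sorted(unknown)}")
    model.validate()
    out: list[BinaryInteraction] = []

    if "IN_SAME_COMPLEX" in rules:
        for cid in sorted(model.complexes):
            genes = [model.gene_of(m) for m in model.flatten_complex(cid)]
            out.extend(_pairs([g for g in genes if g], "IN_SAME_COMPLEX"))

    if "REACTS_WITH" in rules:
        for rid in sorted(model.reactions):
            ins, _outs = model.reactions[rid]
            genes = [model.gene_of(m) for m in ins]
            out.extend(_pairs([g for g in genes if g], "REACTS_WITH"))

    if "STATE_CHANGE" in rules:
        for rid in sorted(model.reactions):
            ins, outs = model.reactions[rid]
            in_genes = {model.gene_of(m) for m in ins} - {None}
            out_genes = {model.gene_of(m) for m in outs} - {None}
            substrates = sorted(in_genes & out_genes)
            if not substrates:
                continue
            for ctrl in model.controllers_of(rid):
                cg = model.gene_of(ctrl)
                if cg is None:
                    continue
                for sg in substrates:
                    if cg != sg:
                        out.append(BinaryInteraction(cg, sg, "STATE_CHANGE"))

    if "SEQUENTIAL_CATALYSIS" in rules:
        for rid_i in sorted(model.reactions):
            _ins_i, outs_i = model.reactions[rid_i]
            for rid_j in sorted(model.reactions):
                if rid_i == rid_j:
                    continue
                ins_j, _outs_j = model.reactions[rid_j]
                # chained by molecule-level identity, not merely same gene
                if not (set(outs_i) & set(ins_j)):
                    continue
                for ci in model.controllers_of(rid_i):
                    for cj in model.controllers_of(rid_j):
                        gi, gj = model.gene_of(ci), model.gene_of(cj)
                        if gi and gj and gi != gj:
                            out.append(BinaryInteraction(gi, gj, "SEQUENTIAL_CATALYSIS"))

    if "CO_CONTROL" in rules:
        for rid in sorted(model.reactions):
            genes = [model.gene_of(c) for c in model.controllers_of(rid)]
            out.extend(_pairs([g for g in genes if g], "CO_CONTROL"))

    return out


def to_network(interactions: list[BinaryInteraction], source: str = "pathway") -> nx.Graph:
    """Collapse interactions into an undirected simple gene graph.

    Rule tags survive as edge annotations; self-edges (homodimer pairs that
    collapsed to a single gene) are dropped.
    """
    net = gr.new_network()
    for bi in interactions:
        gr.add_edge(net, bi.a, bi.b, (bi.rule_tag, source))
    return net


def load_reaction_table(path: str) -> PathwayModel:
    """Parse the line-oriented reaction-table format.

    Record types (tab-delimited)::

        MOLECULE  <id>  <gene_ref or '-'>  [state_label]
        COMPLEX   <id>  <member,member,...>
        REACTION  <id>  <in,in,...>  <out,out,...>
        CONTROL   <controller molecule id>  <reaction id>  <control type>
    """
    model = PathwayModel()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            kind = fields[0]
            try:
                if kind == "MOLECULE":
                    mid, gene = fields[1], fields[2]
                    state = fields[3] if len(fields) > 3 else ""
                    model.molecules[mid] = (None if gene == "-" else gene, state)
                elif kind == "COMPLEX":
                    model.complexes[fields[1]] = fields[2].split(",")
                elif kind == "REACTION":
                    model.reactions[fields[1]] = (fields[2].split(","), fields[3].split(","))
                elif kind == "CONTROL":
                    model.controls.append((fields[1], fields[2], fields[3]))
                else:
                    raise ValueError(f"unknown record type {kind!r}")
            except IndexError as exc:
                raise ValueError(f"{path}:{lineno}: truncated {kind} record") from exc
    model.validate()
    return model
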