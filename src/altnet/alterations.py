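"""Per-case genomic alteration calls and recurrence filtering.

A gene counts as *altered* in a case when it carries a non-synonymous
somatic mutation, a homozygous deletion, or a multi-copy amplification.
Lesser copy-number events (heterozygous loss, single-copy gain) are
recorded but ignored by the frequency score.  Cases flagged as
hypermutators (greatly elevated mutation rate, e.g. after alkylating
chemotherapy) can be excluded before frequencies are computed; the
recurrence filter then keeps genes altered in at least ``min_cases``
retained cases (default 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

STATES = frozenset(
    {
        "NONE",
        "MUTATION",
        "HOMOZYGOUS_DELETION",
        "AMPLIFICATION",
        "HETEROZYGOUS_LOSS",
        "SINGLE_COPY_GAIN",
    }
)

#: states that make a (case, gene) pair count toward recurrence
ALTERED_STATES = frozenset({"MUTATION", "HOMOZYGOUS_DELETION", "AMPLIFICATION"})


@dataclass
class AlterationMatrix:
    """Sparse case x gene state matrix; unlisted pairs are NONE."""

    cases: list[str] = field(default_factory=list)
    states: dict[tuple[str, str], str] = field(default_factory=dict)
    hypermutators: set[str] = field(default_factory=set)

    def state(self, case: str, gene: str) -> str:
        return self.states.get((case, gene), "NONE")

    def genes(self) -> set[str]:
        return {g for (_c, g) in self.states}


@dataclass
class AlteredGeneSet:
    """Genes passing the recurrence filter, with altered-case frequencies."""

    genes: set[str]
    counts: dict[str, int]
    n_cases: int

    def fraction(self, gene: str) -> float:
        return self.counts[gene] / self.n_cases


def load_alterations(path: str, hypermutator_path: str | None = None) -> AlterationMatrix:
    """Load a tab-delimited ``case<TAB>gene<TAB>state`` table.

    An optional header row (first cell ``case``, case-insensitive) is
    skipped.  Identical duplicate rows are idempotent; a (case, gene) pair
    reappearing with a *different* state raises, as does a state outside
    the closed vocabulary.  ``hypermutator_path`` names a plain-text file
    with one case id per line.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, names=["case", "gene", "state"],
        dtype=str, comment="#", skip_blank_lines=True,
    )
    if len(df) and df.iloc[0, 0].lower() == "case":
        df = df.iloc[1:]
    m = AlterationMatrix()
    seen_cases: set[str] = set()
    for case, gene, state in df.itertuples(index=False):
        if state not in STATES:
            raise ValueError(f"unknown alteration state {state!r} for ({case}, {gene})")
        key = (case, gene)
        prev = m.states.get(key)
        if prev is not None and prev != state:
            raise ValueError(
                f"conflicting states for case {case!r}, gene {gene!r}: {prev} vs {state}"
            )
        m.states[key] = state
        if case not in seen_cases:
            seen_cases.add(case)
            m.cases.append(case)
    if hypermutator_path is not None:
        with open(hypermutator_path, "rt", encoding="utf-8") as fh:
            for line in fh:
                cid = line.strip()
                if cid and not cid.startswith("#"):
                    m.hypermutators.add(cid)
                    if cid not in seen_cases:
                        seen_cases.add(cid)
                        m.cases.append(cid)
    return m


def altered_gene_set(
    m: AlterationMatrix, min_cases: int = 2, exclude_hypermutators: bool = True
) -> AlteredGeneSet:
    """Apply the altered-gene definition and the recurrence threshold.

    Counts, per gene, the retained cases in which the gene carries a
    qualifying alteration; genes with count >= ``min_cases`` are kept.
    Genes altered only in excluded hypermutator cases drop out entirely.
    """
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    retained = [c for c in m.cases if not (exclude_hypermutators and c in m.hypermutators)]
    if min_cases > len(retained):
        raise ValueError(
            f"min_cases={min_cases} exceeds the {len(retained)} retained cases"
        )
    retained_set = set(retained)
    counts: dict[str, int] = {}
    counted: set[tuple[str, str]] = set()
    for (case, gene), state in m.states.items():
        if case in retained_set and state in ALTERED_STATES and (case, gene) not in counted:
            counted.add((case, gene))
            counts[gene] = counts.get(gene, 0) + 1
    keep = {g for g, c in counts.items() if c >= min_cases}
    return AlteredGeneSet(
        genes=keep,
        counts={g: counts[g] for g in keep},
        n_cases=len(retained),
    )


def write_frequencies(gs: AlteredGeneSet, path: str) -> None:
    """Write a per-gene frequency TSV (gene, altered-case count, fraction)."""
    rows = [(g, gs.counts[g], gs.counts[g] / gs.n_cases) for g in sorted(gs.genes)]
    pd.DataFrame(rows, columns=["gene", "altered_cases", "fraction"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )
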