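# altnet

Network analysis of recurrently altered cancer genes: connect the genes a
tumor cohort alters through a curated gene-interaction network, keep the
statistically enriched "linker" genes that tie them together, partition the
result into modules, and ask whether the observed connectivity and
modularity could have arisen by chance.

It is a command-line tool and library for cancer genomics groups who have
(a) a gene-interaction network (tab-delimited SIF) and (b) per-case
alteration calls (mutation / homozygous deletion / amplification states),
and who want candidate driver processes rather than a flat gene list.

## Method

1. **Recurrence filter** — a gene is *altered* in a case if it carries a
   non-synonymous somatic mutation, homozygous deletion, or multi-copy
   amplification; hypermutator cases are excluded; genes altered in ≥ 2
   retained cases are kept.
2. **Extraction** — altered-altered interactions are copied from the
   global network; each non-altered gene adjacent to ≥ 2 altered genes is
   tested with an upper-tail hypergeometric p-value (its global degree *n*
   draws from the *N − 1* other network genes, *K* altered), BH-adjusted,
   and retained as a linker when q < 0.05.
3. **Module detection** — Girvan–Newman edge-betweenness removal, scoring
   each step's component partition with Newman modularity
   `Q = Σ_s [ l_s/L − (d_s/2L)² ]` against the original graph and keeping
   the maximal-Q partition.
4. **Null models** — a global random-gene-set null for largest-component
   size (empirical p), and a local degree-preserving rewiring null for
   modularity (the *scaled modularity* z-score).

A reduction front end (`altnet reduce`) also converts simplified reaction
tables (complexes, reactions, controls) into tagged binary interactions.

## Worked example

Generate a synthetic study — a 100-gene background network with three
planted six-gene modules and an 84-case alteration table — then run the
full pipeline on it:

```sh
altnet fixtures --outdir fx --n-genes 100 --mean-degree 4 --seed 17
altnet run --network fx/network.sif --alterations fx/alterations.tsv \
           --outdir out --global-null 200 --local-null 200 --seed 17
cat out/report.txt
```

The report (abridged) prints:

```
cases retained: 84
genes passing recurrence threshold: 21
altered genes placed in network: 20
linker genes retained: 0
altered genes unplaced: 1
largest component: 20 nodes, 46 edges
modules: 3
modularity Q: 0.5792
global null (200 iterations): p_nodes = < 0.005, p_edges = < 0.005
local null (200 iterations): mean Q = 0.2496, sd = 0.0287, scaled modularity z = 11.50
```

Reading it: 21 genes recur in ≥ 2 of the 84 cases; 20 of them
interconnect through the network (one is reported as unplaced), and
module detection splits the extracted network into the 3 planted modules
at maximal modularity (Q = 0.579).  No random gene set of the same size
produced a component as large in 200 draws (p < 0.005), and the observed
modularity sits 11.5 standard deviations above degree-preserving
rewirings of the same network — the planted modular structure is
detected.  `out/` also holds
Cytoscape-loadable files: `network.sif`, node attributes (`role.na`,
`module.na`, `alteration_frequency.na`, `linker_q.na`), edge attributes,
per-module and linker statistics TSVs, and the null distributions.

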