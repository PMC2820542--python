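# Methods

## Problem and model

Tumor genomes accumulate many alterations, only a few of which drive the
disease; a working hypothesis in cancer systems biology is that drivers
concentrate in a small number of densely interconnected processes.  altnet
operationalizes that hypothesis as a four-stage pipeline over an undirected
simple graph of gene-gene interactions (the global interaction network):

1. **Alteration calls and recurrence.**  A gene counts as altered in a case
   when it carries a non-synonymous somatic mutation, a homozygous
   deletion, or a multi-copy amplification; heterozygous losses and
   single-copy gains are recorded but never counted.  Cases flagged as
   hypermutators are excluded before frequencies are computed, and genes
   altered in fewer than `min_cases` retained cases (default 2) are
   dropped.  A gene-case pair with several alteration records counts once.

2. **Subnetwork extraction with linker testing.**  All interactions between
   altered genes are copied from the global network.  With a shortest-path
   threshold of 2, each non-altered gene adjacent to at least two altered
   genes becomes a *linker candidate*; neighbors adjacent to exactly one
   altered gene connect nothing and are pruned before testing.  A candidate
   with global degree *n* and *k* altered neighbors is scored with the
   upper-tail hypergeometric probability P(X >= k) of drawing *k* or more
   altered genes in *n* draws without replacement from the other *N - 1*
   genes of the network (*K* of which are altered) — the self-free urn:
   the candidate is not part of its own population.  Isolated
   network genes count in the population (configurable only by removing
   them from the input).  Candidate p-values are Benjamini-Hochberg
   adjusted across the candidates actually tested, and a linker is
   retained when its q-value is *strictly below* the FDR cutoff (default
   0.05).  Edges among retained linkers are then added.  Altered genes left
   with no retained edge are reported separately rather than kept as
   isolated nodes, since module detection on singletons is vacuous.

3. **Module detection.**  Newman modularity of a partition of a graph with
   L edges is `Q = sum_s [ l_s / L - (d_s / 2L)^2 ]`, with `l_s` the
   within-module edge count and `d_s` the summed degree of module *s*.  The
   Girvan-Newman procedure repeatedly recomputes shortest-path edge
   betweenness on the pruned graph (equal splitting over tied shortest
   paths, unweighted), removes one maximal-betweenness edge, and scores the
   connected components of the pruned graph as a partition of the
   *original* graph.  After all edges are removed the maximal-Q partition
   is returned.  Scoring against the original graph is the standard Newman
   prescription; the search runs globally rather than per component
   (initial components are simply early modules).

4. **Null models.**  The *global* null re-runs extraction on gene sets of
   the observed size sampled uniformly from the network and compares
   largest-component node and edge counts; the empirical p is the fraction
   of iterations meeting or exceeding the observation (`count/iterations`;
   the `(count+1)/(n+1)` correction is available but off by default, and a
   zero count is reported as `< 1/iterations`).  The *local* null rewires
   the extracted network by Maslov-Sneppen double-edge swaps — every node
   keeps its exact degree — re-runs full module detection on each rewired
   graph, and converts the observed Q into the *scaled modularity*
   z = (Q_obs - mean) / sd using the sample (n-1) standard deviation.

A pathway-reduction front end converts a minimal reaction-table format
(molecules with gene references and states, nested complexes, reactions,
controls) into tagged binary interactions under five rule families:
IN_SAME_COMPLEX (pairs among recursively flattened complex members),
REACTS_WITH (pairs among the inputs of one reaction; inputs-only is the
co-substrate reading), STATE_CHANGE (controller to substrate when a
reaction converts between two states of one gene), SEQUENTIAL_CATALYSIS
(controllers of reactions chained by the *same molecule id*, the
conservative state-specific reading of consecutive catalysis), and
CO_CONTROL (controllers of the same single reaction).  Molecules without a
gene reference never generate edges; pairs collapsing to one gene
(homodimers) are suppressed.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_cases` | 2 | recurrence threshold over retained cases |
| `sp_threshold` | 2 | 1 = direct edges only; 2 = also test linkers |
| `linker_fdr` | 0.05 | strict upper bound on linker q-values (0.001 for a stringent, small-input configuration) |
| `global_iterations` / `local_iterations` | 1000 | null-model iterations |
| `swap_multiplier` | 10 | successful swaps per edge in one rewiring (a common mixing heuristic; the method itself fixes no count) |
| `seed` | 0 | master seed; per-iteration streams are spawned by counter so results are independent of execution order |

## Tie-breaking and degenerate inputs

Determinism is fully specified: betweenness ties remove the
lexicographically smallest sorted endpoint pair (ties closer than 1e-9 are
treated as equal); equal maximal Q at several removal counts keeps the
earliest (coarsest) partition; module indices are ordered by decreasing
size then smallest member; all serialized collections are sorted.
Modularity of an edgeless graph is an error, not 0.  Rewiring a graph that
admits no valid swap (stars, near-complete graphs) returns the input
topology with a warning after a bounded number of rejected attempts.  A
degenerate local null (sd = 0) reports the z as undefined rather than
dividing by zero.  A shortest-path threshold beyond 2 is not implemented:
longer paths would require multi-linker chains the method does not define.

The neighbor-expansion algorithm is followed verbatim; the equivalent
"all shortest paths of lengths 1 and 2" framing differs from it only in
how linker-linker adjacency is credited, which is why linker candidacy is
defined by altered neighbors alone.

## Synthetic data

Real inputs are a curated interactome and tumor alteration calls.  The
generator emulates their structure at desk scale: an Erdős–Rényi or
Barabási–Albert background graph (250 genes, mean degree 8 in the standard
study — a scaled-down sparse interactome), three planted six-gene modules
rewired to within-pair density 0.9 and between-pair density 0.05, and a
91-case cohort with 7 hypermutator cases in which planted genes are
altered at rate 0.15 per case (a recurrent driver altered in roughly an
eighth of cases) and background genes at 0.003 (so only a few percent of
background genes reach the 2-case threshold over 84 retained cases,
mirroring the sparsity of real recurrence lists).  States are drawn
uniformly from mutation / homozygous deletion / amplification;
hypermutator cases have rates boosted tenfold.

What the generator does **not** emulate: amplicon structure (shoulder
genes co-amplified along chromosome arms), mutual exclusivity between
drivers of one pathway, degree-correlated alteration bias, or curation
bias in the interactome.  Passing the planted-module benchmark therefore
shows the machinery is correct and well calibrated, not that real-tumor
modules will be as cleanly separable.

## Numerical and design choices

* Hypergeometric tails come from `scipy.stats.hypergeom`, BH adjustment
  from `statsmodels`; tests verify both against independent brute-force
  enumerations (exact combinatorial sums; literal step-up).
* Modularity is evaluated in the grouped form above; tests compare it to
  the explicit pairwise `(A_ij - d_i d_j / 2L)` double loop at 1e-12.
* The max-Q search only visits partitions that arise as connected
  components along the removal sequence, so its Q is bounded below by the
  component partition and above by the exhaustive maximum over all set
  partitions — on dense unstructured graphs it will not reach the
  exhaustive maximum, by construction.  On clearly modular graphs (two
  4-cliques joined by a bridge) it attains it exactly.
* Null iterations default to 1000; the bundled acceptance run uses 200 per
  null, the size at which the planted-structure z (observed ≈ 7–11) and
  the empirical p granularity (0.005) are already stable.
* Reports echo every parameter except the output directory itself, so a
  fixed seed reproduces byte-identical output directories.

## Limitations

Girvan-Newman recomputes betweenness after every removal (O(|E|^2 |V|)),
which is fine for extracted subnetworks (tens of nodes) but not for
partitioning a whole interactome.  Edges are unweighted and undirected;
evidence multiplicity is kept as annotation only.  Identifier namespaces
are the caller's responsibility — tokens are matched verbatim.
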