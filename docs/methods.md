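# Methods

This note documents the statistical procedures implemented in
`panlineage`, the conventions chosen where the procedures admit more than
one reading, and what the synthetic generators do and do not emulate.

## Within-lineage labels and distribution classes

Input is a binary genes × genomes presence/absence matrix and a genome →
lineage map. Genomes without a lineage assignment are dropped with a
warning (collections are routinely restricted to their largest lineages;
genomes outside analysed lineages carry no within-lineage information).
Lineages below `min_lineage_size` (default 1, i.e. no filtering) are
dropped likewise; reproduction-style analyses are expected to pass an
explicit lineage table restricted to the lineages of interest rather than
rely on a size heuristic.

For gene *g* and lineage *l* with *n_l* genomes, the within-lineage
frequency is the exact rational *c/n_l* (carriers over size). Labels:

| label | interval |
|---|---|
| absent | f = 0 |
| rare | 0 < f < `rare_max` (default 0.15) |
| intermediate | `rare_max` ≤ f < `core_min` (default 0.95) |
| core | f ≥ `core_min` |

The nominal bands "up to 15 %", "15–95 %", "more than 95 %" overlap at
the two boundary points; the half-open convention above makes them a
partition. Both cut-offs are parameters, so the strictly-greater reading
of the core boundary is available (e.g. `core_min` slightly above 0.95).
Labelling compares integer carrier counts against rational cut-offs
(`ceil(threshold · n_l)`), never rounded floating-point frequencies, so
boundary cases are exact at any lineage size.

The species-wide class of a gene is a function of its per-lineage label
multiset and the number of analysed lineages *N*: with *p* non-absent
lineages and label set *L*, |L| = 1 gives "collection X" (p = N),
"multi-lineage X" (1 < p < N) or "lineage specific X" (p = 1); |L| ≥ 2
gives the varied class named by the sorted label combination. Genes with
p = 0 (possible when their only carriers sit in dropped lineages) receive
a sentinel `absent` class excluded from 13-class totals. The scheme is
invariant under genome/lineage permutation and under duplicating a
lineage's genomes, and raising `core_min` can only move genes out of
core-containing classes; all three invariants are tested.

## Typical-genome composition

Per genome, carried genes are tallied by class; per lineage, the median
of those tallies; species-wide, the median across the lineage medians.
Even-cardinality medians use the midpoint convention, so summaries may be
half-integers. One source describes this statistic as a "weighted
median" in passing while operationally defining the nested median; the
nested median is implemented since it is the operational definition.
Fractions are normalised by the typical genome's total count.

## Lineage-tree analyses

**Patristic distances** are path-length sums between leaves on the
rooted, fully branch-length-annotated lineage tree (via dendropy); a
missing branch length is a validation error rather than an implicit zero.

**Lineage presence** for tree analyses is deliberately frequency-free: a
gene is present at a leaf as soon as one genome of the lineage carries
it, so rare within-lineage observations still register as occupancy.

**Ancestral reconstruction** is minimum-change (Fitch/Sankoff parsimony
with unit costs) over the binary presence character, with ambiguities
resolved by accelerated transformation. Implementation: a binary Sankoff
downpass computes, per node and state, the minimal change count of the
subtree (polytomies handled natively by summing over children); the root
takes the cheaper state, resolving exact ties to **absent** — this reads
a phyletically restricted gene as gained within the tree rather than
ancestrally present and repeatedly lost, and is configurable
(`ambiguous_root_state`). A preorder pass then gives each node the state
minimising branch-change-plus-subtree cost given its parent's final
state, breaking exact ties toward the state *opposite* the parent. The
tie-break is what accelerates transformations: an ambiguous node absorbs
the change on its own (rootward) branch instead of deferring it to its
children. Because every node is resolved independently and
deterministically, no further tie-breaking between children is needed;
the procedure is reproducible and invariant to child order. Total
gains + losses per gene equals the parsimony score (verified against
exhaustive enumeration over internal labelings on random trees, including
polytomies). Branches are reported under the name of their child node.

## Gene sharing between lineages

The raw sharing count of a lineage pair is the number of genes of the
selected distribution classes (default: `intermediate and rare`, where
mobile-element cargo concentrates) with at least one carrier in both
lineages. Two corrections:

* **Relatedness**: pairs at patristic distance < `distance_threshold`
  (default 0.15) are excluded, so sharing by recent common descent is not
  read as transfer.
* **Sample size**: each lineage is subsampled to `subsample_size`
  genomes (default 20) without replacement, counts recomputed on the
  reduced matrix, repeated `n_repeats` times (default 40); the mean over
  repeats is the corrected count. Class labels are *not* recomputed
  inside subsamples — the full-data classification defines each gene's
  class, since subsampling corrects the counting, not the classification.
  Lineages smaller than the subsample size are excluded with a warning
  (sampling with replacement would change the estimand). Each repeat uses
  an independent substream seeded by (seed, repeat), making results
  bit-reproducible and order-independent.

**Outlier lineages**: each lineage's corrected pair counts are compared
against all pair counts not involving it by a two-sided Mann–Whitney
rank-sum test (exact for small tie-free samples, normal approximation
with tie correction otherwise; all-equal degenerate input yields p = 1 by
convention), Benjamini–Hochberg adjusted across lineages. The package
also exposes a per-isolate view (`per_isolate_sharing`) counting selected-
class genes per genome, for isolate-level group comparisons; the pairwise
lineage comparison is the primary documented analysis.

**Size regression**: ordinary least squares of log(count + 1) on the
smaller lineage size of each pair. The +1 offset admits zero counts and
is stated here because "log-linear regression" alone does not fix the
zero handling.

## Annotation summaries

COG categories are cross-tabulated against classes; unannotated genes
count under `?`. Free-text functional predictions are lower-cased,
whitespace-tokenised, stopwords removed, and every contiguous run of ≥ 2
retained words is one sub-sentence (a run may bridge an elided stopword).
The documented worked example — "atp-binding component of a transport
system" yielding exactly three sub-sentences — corresponds to contiguous
runs, not arbitrary word combinations (which would also produce
"atp-binding transport"), so contiguous runs are implemented. Per class,
sub-sentence counts are merged: where one entry's word sequence contains
another's and counts differ by ≤ `merge_delta` (default 3), the shorter
is dropped and the longer kept with its own count. Processing entries
longest-first makes the merge deterministic and idempotent and leaves no
nearly-equal nested pair behind (tested). The default stopword list is a
small set of English function words plus a few generic annotation
fillers; it is explicitly user-replaceable and no analysis depending on
its exact contents is treated as a reference result.

## Synthetic generators

`plant_pangenome` realises prescribed per-lineage labels exactly:
representative carrier counts per label (all genomes for core, ~half for
intermediate, the largest count strictly below the rare cut-off for
rare), carriers drawn seed-deterministically. The default layout gives
one lineage half of all genomes — the over-sampling scenario the
classification exists to handle — and the default gene panel is one gene
per class. At zero noise, classification recovers every planted class
exactly; with cell-flip noise the truth table remains the intended
reference. The generator emulates the *combinatorial* structure of real
collections (class composition, skewed lineage sizes), not their linkage:
cells are independent given the planted frequencies, there is no
phylogenetic autocorrelation of carriage within lineages, and no
gene-gene co-occurrence (operons, plasmids). Perfect recovery on planted
data therefore validates the classification logic, not robustness to the
correlated noise of real pan-genome pipelines.

`mobile_gene_collection` builds the sharing test-bed: 47 lineages with
log-spaced sizes from 20 to 400 genomes (few large, many small — chosen
to mirror the lineage count of a large single-species clinical collection
and to yield > 100 analysable pairs), 400 mobile genes carried by every
genome independently with per-gene probability uniform on
[0.003, 0.03], plus ubiquitous core background. Independent per-genome
carriage makes the probability a lineage contains a carrier grow with
lineage size (raw sharing correlates with size by construction, log-scale
R² ≈ 0.6 at these settings) while any fixed-size subsample has a
size-independent carrier distribution — so the subsampling correction
provably removes the entire size signal, and residual correlation in the
corrected counts is pure sampling noise.

`simulate_gain_loss` evolves presence along a (given or birth–death
simulated) tree as a two-state Markov jump process with exponential
waiting times; branches without lengths evolve over length 1; the root
state is Bernoulli with the stationary probability unless pinned. The
true event log is returned per branch. Reconstruction recovers exact
per-gene event counts only when repeat events on a branch are improbable;
the recovery test uses rates giving ~0.3 expected events per gene, where
agreement exceeds 95 %.

## Problem sizes and numerical conventions

Test and reference computations run on deliberately small inputs: planted
collections of 600–6000 genomes, trees of 4–10 leaves for
enumeration-based oracles (exhaustive scoring is exponential in internal
nodes), 40 subsampling repeats matching the published configuration. The
classification itself is a single integer matrix product plus
thresholding and scales to collections orders of magnitude larger.

Known limitations: ACCTRAN tie resolution is one of several defensible
conventions (the choice is declared above and configurable at the root);
the sub-sentence stopword list is not canonical; full-collection
reproduction of published E. coli class counts requires the original
collection files and is out of scope for the bundled tests, which are
property-based throughout.
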