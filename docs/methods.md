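# Methods

## The annotation model

A matrix cell is one of five exclusive states. `na` (not analyzed) is a
first-class state, not missing data: it records that an ISH signal could
not be read reliably in that tissue, and it is bookkept separately from
`negative` everywhere (summary tables, sieve predicates, rank
correlations). A gene is *expressed* in a tissue when its state is weak,
medium or strong, so for every tissue
`n_na + n_negative + n_expressed = n_genes`.

Ordinal encoding uses `negative→0, weak→2, medium→3, strong→4`, the
convention of the scoring scheme this package models. The gap between 0
and 2 is kept verbatim rather than "repaired" to 0/1/2/3: every downstream
consumer is rank-based, and a property test asserts that any strictly
monotone recoding leaves the Spearman matrix unchanged.

### Percentage rounding

Summary percentages are computed as `(100 * count) / total` in IEEE double
precision and rounded to one decimal with round-half-to-even on the double
(`%.1f` semantics). With counts out of 2000 every value is an exact tenth
or a `.x5` tie, and ties resolve through the binary representation — e.g.
785/2000 → 39.2 but 1017/2000 → 50.9. This exact rule, including the
operand order (the product before the division), is what reproduces the
published per-tissue summary table cell for cell; computing
`count/total*100` instead changes 17 of the 150 cells.

## Sieve semantics

A query is an AND/OR tree over leaf predicates `(tissue, accepted state
set)`; the text grammar is `TISSUE (is|in) STATES` with `expressed` as
sugar for `{weak,medium,strong}`, AND binding tighter than OR, and
parentheses. Two deliberate choices:

- `na` never satisfies `expressed` or a named level unless listed
  explicitly — an unreadable signal is not evidence of anything;
- there is no NOT operator. Complement exists only at the gene-list level
  against an explicit universe, which keeps every sieve result a subset of
  the originating matrix's genes and makes De Morgan identities testable
  rather than implicit.

## Tissue dendrograms

Correlation is Spearman's rank coefficient per tissue pair, computed on
the genes unmasked in *both* tissues (pairwise-complete; a pair sharing
fewer than 3 genes is an error naming the pair), with average ranks for
the heavy ties ordinal data produces. Pairwise deletion maximizes the
usable data and matches the per-tissue `na` bookkeeping; it can in
principle make the distance matrix slightly non-Euclidean, which the tree
engine tolerates.

Dissimilarity is `d = 1 − ρ` (range [0, 2]), the standard correlation
dissimilarity: it preserves the similarity ranking and needs no
renormalization.

The tree engine is canonical neighbor joining: minimize
`Q(i,j) = (n−2)d(i,j) − r_i − r_j`, with exact ties broken toward the
lowest (row, column) pair so output is deterministic, and negative
branch-length estimates clamped to zero. NJ is used as the distance-tree
engine because it is consistent — on additive input it recovers the
generating topology and branch lengths exactly, which is how the engine is
validated (100 random 4–8-taxon additive matrices, plus agreement with an
exhaustive OLS minimum-evolution search over all 15 topologies on 5-taxon
cases, plus a cross-check against an independent NJ implementation).
Balanced minimum-evolution search with NNI rearrangements is out of scope.
`cut_tree(tree, k)` partitions leaves by removing the k−1 longest internal
branches; it is a labelled longest-branch heuristic, not a reimplementation
of any model-based dendrogram partitioner.

## Interactome zooming

Confidence scores live on a 0–1 scale (a loader flag divides STRING-style
0–1000 integers by 1000); retention is strictly `confidence > threshold`
with 0.7 as the conventional high-confidence default. Self-loops are
dropped and duplicate pairs collapse to the maximum confidence.

Zoom node sets are defined purely by counts of *distinct* query neighbors:
L1 needs ≥1, L2 needs ≥2, L3 admits only query genes. Edges at every level
are the induced subgraph on the selected nodes — this includes edges among
non-query neighbors at L1/L2, the natural choice when a node selection is
handed to a graph renderer, and it keeps the levels purely node-defined
with the nesting invariant L3 ⊆ L2 ⊆ L1. `seed_zoom` is a per-gene
convenience: the query becomes one seed gene plus its direct partners
inside a list, then a normal zoom runs — an interpretation of
"neighborhood network of one gene", flagged as such. Components are
reported largest-first with lexicographic tie-breaks.

## Fold enrichment and disease linkage

For lists A and B, each GO term attached to any gene of A ∪ B gets
`fold = pct_A / pct_B` with `pct_X = 100·count_X/|X|`. Deliberately
absent: p-values, multiple-testing correction, and GO-DAG ancestry
propagation — the statistic modeled here is the raw percentage ratio over
terms as listed, and adding inference machinery would change what the
numbers mean. Terms present in A but absent from B carry an infinite-fold
flag and are excluded from rankings by default. The default aspect filter
is molecular function. `min_pct` is a display threshold only.

Morbidmap records (`disorder | gene symbols | MIM | cyto`, pipe or tab
dialect) are indexed under every listed gene symbol; malformed rows are
skipped with a logged warning since real morbidmap exports are noisy.

## Synthetic data

The generators exist because the real atlas matrix and its frozen
interactome snapshot are not distributable; they emulate the *statistical
structure* the analyses rely on, not the biology.

**Annotation matrices** use a latent-factor-plus-threshold construction,
chosen over copulas for transparency and exact marginal control. Per gene
and tissue block, a latent intensity
`x = √s·z_block + √(1−s)·ε` (marginally N(0,1), within-block correlation
`s`) is cut at quantile thresholds. The thresholds are solved
*conditionally* so that after layering in (i) the forced never-expressed
subset (exactly `round(f·n)` genes set negative everywhere, default
f = 0.165, the published fraction) and (ii) the NA mask (per-cell
Bernoulli at the tissue's NA marginal), the unconditional state
frequencies hit the targets; marginals below the never-expressed floor
raise an infeasibility error. The `table1` preset uses the published
per-tissue marginals, three blocks matching the published dendrogram
branches (inner-ear, mesodermal/skeletal, neural+skin-derived), and block
strength 0.6 — strong enough for reliable branch recovery at 2000 genes,
weak enough that recovery is a real statistical test rather than a
tautology. The real data's inter-tissue correlations are unpublished, so
block strength is a free parameter, not an estimate.

**Interactomes** are planted-partition graphs (contiguous modules,
`intra_p > inter_p`) with intra-module confidences drawn from (0.71, 0.99)
and inter-module from (0.15, 0.85), so the 0.7 threshold retains mostly
intra-module edges. **GO tables** give exactly `round(nogo·n)` genes no
terms (default 18.3%, the published NoGO fraction) and Zipf-skewed term
popularity so a few terms dominate as in real molecular-function
distributions. **Morbidmaps** link exactly `round(0.12·n)` genes, with
occasional 2–3-symbol rows exercising multi-gene indexing.

All generators are pure functions of (config, seed); one master seed fans
out to per-component child streams via `SeedSequence` spawn keys, so adding
a generator never perturbs another's draws.

What passing on synthetic data does **not** show: the latent-Gaussian
block model is exchangeable within blocks and has no gene-level structure
(no pathway co-regulation, no tissue-specific annotator bias, no spatial
pattern information), the interactome has no degree heterogeneity or hubs,
and GO terms are independent of expression. Atlas-scale headline counts
that depend on the real joint distribution (e.g. the size of the
five-tissue co-expressed set or its network decomposition) are therefore
covered by construction-level and oracle-level tests, not by asserting
those published values.

## Problem sizes and numerical notes

The validation suite runs 200 random sieve and 200 zoom oracle
comparisons, 100 additive-matrix tree recoveries, and 20 seeded
2000-gene × 25-tissue replicates for planted-block monophyly — sizes
chosen so the full pipeline is exercised at atlas scale while a complete
run stays in the tens of seconds. Monophyly of a block in the unrooted
tree means the block is one side of some bipartition. Distance matrices
are validated to 1e-12 symmetry; additive recovery is asserted at 1e-9 on
path lengths; Spearman against the naive rank-then-Pearson oracle at
1e-12. Gene identifiers are case-folded for joins across modules, with
original spelling preserved for display.
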