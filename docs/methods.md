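# Methods

## The association model

`mirdmap` treats miRNA–disease association as the relational composition
of two curated binary relations: a miRNA targets a gene, and a gene is
implicated in a disease, hence the miRNA is (putatively) associated with
the disease. Formally, with A ⊆ miRNA×gene and B ⊆ gene×disease, the
derived relation is A∘B = {(m, d) : ∃g, (m, g) ∈ A ∧ (g, d) ∈ B}. The
composition and its transpose form the bidirectional store
(`AssociationDB`), whose key universes M_N (miRNAs) and D_N (diseases)
are the denominators and totals of every downstream statistic.

Identity of entities is the literal name string after stripping
surrounding whitespace: no case folding, no Unicode normalisation, no
vocabulary mapping (disease names from different sources that differ only
in phrasing stay distinct). Queries, by contrast, are case-insensitive
unanchored regular expressions in the Python `re` dialect. miRNAs whose
target genes carry no disease annotation drop out of the composition;
their count is always reported, since it is the natural sanity check of a
gene-key merge.

Associations are sets, not multisets: a duplicate row in a source table,
or two gene paths to the same disease, contribute one association. All
counts downstream (spectrum widths, contingency cells, diseasome
occurrences) are therefore set cardinalities.

## Spectrum widths

DSW(i) = d_i / D_N and MSW(j) = m_j / M_N, with d_i the associated-disease
count of miRNA i and m_j the associated-miRNA count of disease j, both
over the *merged* database universes — never the sizes of the source
layers. Internal values are kept at full double precision; report
formatting rounds half-up to two decimals (`format_width`), matching the
convention of published ranking tables. Ranking ties break
lexicographically by name so output is reproducible byte-for-byte.

## Enrichment statistics

For a deduplicated, database-resident query Q and disease with miRNA set
S, the 2×2 table over the M_N universe is a = |Q∩S|, b = |Q|−a,
c = |S|−a, d = M_N−a−b−c. Significance is the one-sided upper-tail
hypergeometric probability P(X ≥ a) with X ~ Hypergeom(M_N, a+c, a+b) —
identical to the one-sided Fisher exact test. It is computed with
`scipy.stats.hypergeom.sf`; the test suite verifies agreement with exact
rational enumeration to better than 1e−12 over every table with n ≤ 60.
An underflowed p is clamped to the smallest positive double so p ∈ (0, 1]
holds throughout.

The effect size is the unconditioned sample cross-product ratio
(a·d)/(b·c), reported with explicit sentinels: `Inf` when a·d > 0 and
b·c = 0 (in particular b = 0, i.e. the entire query is contained in the
disease's miRNA set), 0 when a·d = 0 and b·c > 0, and `NA` for the
indeterminate 0/0. No Haldane–Anscombe continuity correction is applied —
the sentinel cases are informative and are preserved in output. The
log2 odds ratio is reported alongside and propagates the sentinels.

The hypothesis family is **all** D_N diseases in the database, not only
those overlapping the query; q-values come from Bonferroni, Holm, or
Benjamini–Hochberg (default) correction, all computed by
`statsmodels.stats.multitest.multipletests` behind the module surface and
cross-checked against hand-coded textbook implementations in the tests.
Default reporting threshold is q ≤ 0.05. Query names are matched to
database keys case-insensitively, since miRNA capitalisation is
notoriously inconsistent in the literature; unresolvable names are
dropped with a warning and an all-unknown query is a hard error.

Because the hypergeometric test is discrete, raw p-values are
super-uniform under the null (P(p ≤ t) ≤ t), markedly so for small
tables. The null-calibration check therefore runs in a regime where the
null distribution is effectively continuous — a 6,000-miRNA universe with
query sizes of 2,000–4,000 — where 1,000 random queries pass a
Kolmogorov–Smirnov uniformity test and the rejection rate at p ≤ 0.05
sits within three binomial standard errors of 0.05. At desk scale
(hundreds of miRNAs, queries of a handful), the same statistics are
conservative, not anti-conservative; this is inherent to exact discrete
tests, not an implementation artefact.

## Diseasome profiling

A diseasome is selected either by explicit names (resolved
case-insensitively, unknowns reported) or by keyword regex. The abundance
profile counts, per miRNA, the number of diseasome diseases containing it
— occurrence counting only, no weighting by multiplicity and no
significance test (enrichment lives in its own module). The default
occurrence threshold is 1 and the threshold used is always reported.

## Overlap-enrichment networks

The pairwise score of two miRNAs is the same one-sided Fisher test
applied to the overlap of their disease sets against the D_N universe
(symmetrically for disease pairs over M_N). This makes the adjacency
construction exactly the enrichment machinery applied to node pairs, and
the resulting matrix symmetric. All N(N−1)/2 unordered pairs are scored
(vectorised through `hypergeom.sf`), BH correction runs across the full
family of scored pairs, edges with q ≤ α (default 0.05) are retained,
ranked by −log10 p descending, and truncated to the top k (default
10,000). Tie-breaking is p ascending, then odds ratio descending among
p = 0 underflows (−log10 p capped at 320), then lexicographic node names,
so the edge list is byte-stable across runs and node orderings. Export is
a plain TSV (source, target, weight, p, q, neg_log10_p) importable by
Cytoscape's edge-table reader, with `Inf`/`NA` literals for the
odds-ratio sentinels.

Both the significance filter (α) and the truncation (k) are exposed;
either can be disabled by setting α = 1 or k large.

## Centrality and consensus hubs

The hub analysis consumes the exported edge list as an undirected simple
weighted graph. Infinite odds-ratio weights are replaced by the maximum
finite weight in the network (configurable), so all weights are finite
and positive. Measures:

- **degree** — sum of incident edge weights;
- **betweenness, closeness** — shortest paths under distance = 1/weight
  (stronger enrichment = closer); computed per component, isolated nodes
  score 0;
- **eigenvector** — principal eigenvector of the weighted adjacency by
  power iteration (tolerance 1e−10), non-negative, unit max-norm;
- **network centrality** — NC(v) = Σ_{u∈N(v)} ECC(u,v), with ECC the
  edge clustering coefficient: the geometric-mean-weighted triangle count
  through the edge over min(deg_u, deg_v) − 1, defined as 0 for pendant
  edges where the denominator vanishes (no triangle is possible there);
- **local average connectivity** — LAC(v) = mean degree of v's
  neighbours within the subgraph they induce;
- **information** — current-flow closeness with edge weights as
  conductances, per connected component.

Degree, betweenness, closeness, eigenvector-by-power-iteration and
information go through networkx; network centrality and LAC are
implemented here, as no networkx equivalent exists. Ranks within a
measure break ties lexicographically. A node's agreement is the number of
measures whose top-T list (default T = 100) contains it; consensus hubs
have agreement ≥ 5 by default.

Edge-percolation centrality is a separate, explicitly stochastic measure:
each replicate retains every edge independently with probability
`retain · w_e/max(w)` (base retention 0.5, so even the heaviest edge can
fail), and a node's score is its mean percolated connectivity — the
number of other nodes in its component — over the replicates (default
1,000, seeded, deterministic given graph/reps/seed/retain). The retention
normalisation is a design choice of this package; EPC is reported with
its replicate count and seed and is excluded from exactness guarantees.

## Synthetic fixtures

The generator draws the two mapping layers as independent Bernoulli edge
matrices and overlays planted structure, only ever adding edges (so the
densities are lower bounds). Defaults — 80 miRNAs × 120 genes × 60
diseases at 3% density per layer — give a merged miRNA–disease density
near 10%, sparse enough that planted structure separates cleanly from
background. Plantings:

- **hub** — one miRNA wired to a stated fraction of all genes; with
  fraction 0.9 it attains the top DSW after the merge;
- **enriched disease** — a disease attached to one target gene per
  member of a random query set (the least-shared target, or a private
  marker gene if the member has none), guaranteeing the query is
  contained in the disease's miRNA set (b = 0, odds ratio `Inf`) while
  keeping bystander pickup minimal; the planted disease ranks first in
  the enrichment output in ≥95 of 100 seeds at the default spec;
- **cliques** — blocks of miRNAs sharing a private battery of 10 genes
  mapping to 16 private diseases, so block members have near-identical
  disease sets and their pairs dominate the overlap-network ranking.

What the fixtures do *not* emulate: the heavy-tailed degree distributions
of real curated databases, vocabulary structure in disease names, and
correlated curation biases. One real phenomenon they *do* reproduce, by
construction: background miRNAs that share even one high-fan gene acquire
near-identical disease sets, so the background occasionally grows its own
high-overlap pairs. Planted-structure tests therefore rely on margin
(battery size) rather than on the impossibility of background signal, and
network-recovery checks compare against the top-k ranking, not against
"no other edge is significant". Passing tests show the machinery is
correct on data of this shape; they do not certify biological conclusions
drawn from any particular pair of curated sources.

## Numerical and determinism choices

- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; generation is a pure function of the fixture spec.
- Sorting everywhere uses total, deterministic keys (score, then name),
  so every output table and TSV is byte-stable across runs and input
  orderings.
- p-values are clamped to (0, 1]; −log10 p is capped at 320 for
  underflows.
- Report rounding is half-up via `decimal`; internal values are never
  rounded.
- Test-suite problem sizes: exhaustive Fisher-oracle grid at n ≤ 60
  (~6.4×10⁵ tables), join oracles at hundreds of pairs per instance,
  networks at ≤ 80 nodes, calibration at a 6,000-miRNA universe — chosen
  so the full suite completes in about two minutes on one core.

## Known limitations

- Disease names are used verbatim; near-duplicate vocabulary entries
  ("Mental retardation" vs "Mental deficiency") count as distinct
  diseases, inflating D_N relative to a concept-normalised resource.
- The gene-key composition inherits every curation error of its inputs
  and asserts only guilt-by-association, not mechanism.
- The discrete enrichment test is conservative for small queries and
  small databases (see calibration note above).
- EPC depends on a package-chosen retention normalisation; its absolute
  scores are not comparable across tools, only its ranking is meaningful
  within a run.
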