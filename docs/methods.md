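# Methods

## Data model and harmonization

The pipeline's atom is one (source, disease, gene) evidence row. Three
source dialects are parsed:

* **Orphanet XML** — `<Disorder id="…" omim="…">` elements with a name and
  a gene list. The dialect is a minimal fixture schema carrying exactly the
  fields the pipeline consumes (disease id, name, genes, optional OMIM
  cross-reference); readers ignore unknown sibling elements, so files with
  extra annotation still parse. Disorders missing an id or name are
  record-level errors (skipped and tallied), not fatal.
* **OMIM genemap TSV** — only rows with phenotype mapping key **3** are
  kept (molecular basis known; mutations found in the gene). Both the bare
  `3` and OMIM's parenthesized `(3)` spelling are accepted; any other key
  drops the row, and a non-integer key is a record-level error.
* **DisGeNet TSV** — diseases keyed by UMLS CUIs are re-keyed to OMIM
  identifiers through a CUI→OMIM map. A CUI resolving to two or more OMIM
  ids is ambiguous and its rows are discarded (counted); unmapped CUIs are
  counted separately. This is a deliberately strict rule: an identifier
  whose disease identity is uncertain would contaminate the merge.

Gene mentions are normalized to HGNC official symbols case-insensitively
through an alias table; official symbols resolve to themselves, unmapped
symbols are **retained verbatim** (flagged, with the unmapped fraction
logged) rather than dropped, since discarding them would silently shrink
gene sets. Normalization is idempotent.

Merging collapses identical (disease, gene) pairs across sources into one
row with the union of provenances — deduplication at pair granularity
preserves evidence while removing redundancy. Orphanet disorders
cross-referenced to an OMIM id adopt the OMIM id as canonical identity;
without this the cross-source disease overlap would be structurally zero.
Disease names follow source precedence Orphanet > OMIM > DisGeNet
(first-seen wins inside a level; conflicts logged).

Category assignment is by source membership: Orphanet-only → OD,
non-Orphanet-only → CD, both → BOTH. Where a study must place
dual-membership diseases on one side, note that BOTH diseases here
participate in *both* bipartite layers; this is a declared convention of
this package, since membership rules for such diseases are genuinely
underdetermined, and exclusive assignment can be recovered by filtering
the category column of the integrated table.

## Networks and topology metrics

Gene–disease bipartite graphs contain the diseases of one category (plus
BOTH) and their genes; one edge per unique pair. Being bipartite they are
triangle-free, so every local clustering coefficient — and hence the
network clustering coefficient — is exactly 0; the test suite asserts this
on every synthetic run as a structural guarantee.

The diseasome projection links diseases sharing at least `min_shared`
genes (default 1; the stricter view uses 10). Edges carry the shared-gene
count as weight and the shared symbols themselves, so every projected edge
can be re-derived by set intersection — the tests do exactly that.

Per-node metrics follow the NetworkAnalyzer conventions, which differ in
small but consequential ways from some library defaults:

* distances are BFS hop counts within components;
* **closeness** is 1 / (mean distance to *reachable* nodes), 0 for
  isolated nodes (no small-component rescaling);
* **radiality** is (Δ + 1 − mean distance)/Δ with Δ the diameter of the
  node's component, defined as 1.0 for isolated nodes by continuity
  (Δ = 0);
* **betweenness** and **stress** count unordered source–target pairs;
  betweenness is normalized by (n−1)(n−2)/2 with n the *whole-graph* node
  count even in disconnected graphs;
* **stress** is the raw number of shortest paths passing through the node.

Betweenness and stress are computed in one Brandes accumulation pass per
source (stress uses the σ-weighted dependency variant); the pass also
yields eccentricity, closeness and radiality. Nodes are processed in
sorted-id order so floating-point accumulation is bit-reproducible.
Correctness is checked two ways: against networkx's betweenness and
against brute-force enumeration of all shortest paths on hundreds of
seeded random graphs.

The whole-network summary panel defines `shortest_paths` as the number of
connected **ordered** (s, t) pairs and the characteristic path length as
the mean distance over exactly those pairs (disconnected pairs excluded,
not infinite); density is 2E/(n(n−1)), average neighbors 2E/n, and
heterogeneity the coefficient of variation of the degree distribution
(population variance). Top-hub rankings break ties by ascending node id
so output is deterministic.

## Disease–pathway enrichment

For a disease with gene set D and a pathway P inside a universe U:
N = |U|, K = |P ∩ U|, n = |D ∩ U|, k = |D ∩ P ∩ U|, X ~ Hypergeom(N, K, n).
The two-sided p is the doubled smaller tail,
p = min(1, 2·min(P(X ≥ k), P(X ≤ k))), with the direction (enriched or
depleted) given by the smaller tail; ties count as enriched so they are
never silently dropped by the enriched-only edge filter. A
minimum-likelihood two-sided definition (sum of all outcomes no likelier
than k) is available via `method="minlike"`. Tail probabilities come from
scipy's hypergeometric distribution, which computes in log-space; the test
suite verifies agreement with exact integer enumeration over the entire
parameter lattice N ≤ 50 at relative 1e-10.

The default universe is the union of the pathway gene sets (the annotated
universe conditioning of the classic hyperGTest idiom); `universe`
widens it to all integrated genes. The Bonferroni family is the pathway
collection, applied per disease (adj_p = min(1, p·m), m = number of
pathways) — matching the per-disease testing loop the pipeline runs, not a
global family across all disease×pathway tests. Untestable diseases (no
gene in the universe) yield no records. Network edges require an
*enriched* direction and adj_p ≤ α (default 0.05; α = 1.0 is allowed as
the boundary case that keeps every enriched record). (OD, CD, pathway)
triples enumerate all OD×CD pairs attached to one enriched pathway, a
disease labeled BOTH serving on either side but never paired with itself.

## Synthetic data

The generator draws, per master seed, from independent substreams
(pathways, disease gene sets, alias emission), so changing one facet never
perturbs the others — this is what makes the "alias noise is invisible
after normalization" guarantee testable with byte-level strictness.

Defaults, chosen once as a realistic desk-scale miniature of a
gene–disease corpus: 200 genes, 30 orphan diseases (3–15 genes each,
oligogenic), 60 complex diseases (10–60 genes), 5 DisGeNet-only diseases,
20 pathways of 10–40 genes, 50% cross-source duplication, 10% alias noise,
10% ambiguous CUIs. Pathway membership first deals every gene to one
pathway (so the annotated universe is the whole gene pool), then tops each
pathway up to its drawn size. The full pipeline on this scale runs in
well under a second.

Planted enrichment is exact set construction: a planted disease draws
exactly k* genes inside its target pathway and the rest outside, so the
ledger is guaranteed by construction rather than by sampling luck.
Infeasible plantings (k* exceeding the pathway size or the disease's gene
count) raise before any file is written.

The truth ledger records per-source pair counts, the merged pair count,
all seven Venn region counts, OD/CD gene-set sizes and overlap, disease
categories, the exact diseasome edge lists at each threshold in
`min_shared_grid`, and the planted triples.

What the generator does **not** emulate: real Orphanet/OMIM record quirks
beyond the parsed fields, realistic disease nomenclature or gene-symbol
distributions, literature-biased gene–disease degree distributions
(synthetic gene sets are uniform draws), or overlapping disease ontologies.
Passing tests therefore demonstrate correctness of the computations and
bookkeeping under controlled conditions, not robustness to every
real-snapshot formatting anomaly.

## Calibration and validation design

* **Type-I error of the enrichment stage** is measured on 200 null bundles
  (no planted signal). The doubled-tail test on a discrete distribution is
  conservative: for small gene sets (n, K ≲ 30 of N = 200) its attainable
  size is ≲ 0.02. The calibration fixtures therefore draw disease gene
  counts and pathway sizes from 40–90 against the 200-gene universe, where
  the analytic size of the test averages ≈ 0.03–0.05, so the measured
  false-positive fraction is informative about calibration rather than
  about discreteness. This choice follows from the analytic size
  computation, not from tuning against observed outcomes.
* **Planted recovery** uses k* = 8 of a disease's 12 genes inside a
  15-gene pathway (N = 200, 20 pathways): the enrichment tail is ≈ 1e-9,
  so the planted edge must survive Bonferroni at α = 0.05 in essentially
  every seed; 200 seeds are checked, along with the structural guarantee
  that no depleted record ever becomes an edge.
* **Centrality panel**: 200 seeded Erdős–Rényi graphs (5–30 nodes) against
  brute-force all-shortest-path enumeration at 1e-9.
* **Round trip**: 50 generated bundles across a grid of overlap, ambiguity
  and noise fractions are pushed through ingest + integrate and must
  reproduce the ledger's merged-pair and Venn counts exactly.

Problem sizes throughout (bundle scale, 200-seed calibration loops,
N ≤ 50 exhaustive lattice) are chosen so the full validation suite runs in
about a minute on one CPU while still exercising every code path at
non-toy scale.

## Known limitations

* Disease identity resolution relies on explicit OMIM cross-references;
  no ontology- or name-based reconciliation is attempted.
* Only Bonferroni adjustment is provided; FDR-style procedures are out of
  scope.
* Only gene symbols are handled (no Entrez/Ensembl resolution).
* Graphs are undirected and unweighted for path purposes; edge weights on
  the diseasome are annotations, not shortest-path costs.
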