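# Methods

## Model

Over-representation analysis treats a query gene set as an unordered draw of
size *n* from a background universe of *N* genes, of which *K* carry a given
functional term. The overlap *k* between query and term is then
hypergeometric, and the reported p-value is the exact upper tail
P(X ≥ k). The one-sided (greater) Fisher exact test conditions on the same
margins and is mathematically the same number; both are offered because both
names circulate in practice, and the test suite asserts their identity to
1e−12 relative on every valid table up to N = 60. Only enrichment
(upper-tail) is tested; depletion is out of scope.

Independence between genes is assumed, as in all ORA: co-regulated or
paralogous genes violate it, so p-values on real data are anti-conservative
to an unknown degree. This is a property of the method, not of this
implementation.

### Numerical route

Both tests run in log space. The hypergeometric pmf is assembled from
log-binomials via `gammaln`; the upper tail is a reverse cumulative
log-sum-exp over the support (`np.logaddexp.accumulate`), so the smallest
attainable p-values (down to ~1e−300) survive without underflow. The Fisher
route instead computes each table's conditional probability from the
margin/cell factorial formula — a deliberately distinct computation, so the
route-agreement check in the tests is informative. k = 0 (or k at the bottom
of the support) returns exactly 1.0, never 1-ε. q = 0 never occurs, but
plotting floors q at 1e−300 and caps −log10 q at 300 to keep axes finite.

### Multiple testing

Benjamini–Hochberg step-up is the default (`FDR` and `fdr_bh` are aliases,
reflecting the common usage in which "FDR" names the BH procedure);
Benjamini–Yekutieli (harmonic-factor correction for arbitrary dependence)
and Bonferroni are selectable. The correction family is exactly the set of
tested terms: terms excluded by the size filters do not inflate m.
Adjustment happens after all filtering, and removing a term via filters
changes every q-value precisely as recomputing the step-up on the reduced
vector (asserted against an independent longhand implementation and
statsmodels).

## Library construction

A library is `term → set of official gene symbols` for one species and one
database, plus term names, category labels and the species universe.

**GO path.** The ontology comes from an OBO 1.2 file; only `id`, `name`,
`namespace`, `is_a`, `relationship: part_of`, `alt_id` and `is_obsolete`
are read. Propagation follows `is_a` and `part_of` (the standard GO
convention; `regulates`-family relations are ignored), crosses namespaces as
written in the file, and is memoized so building is one graph traversal
overall. Acyclicity and closure (no dangling parents) are validated at parse
time with explicit error reports. Obsolete terms are retained and flagged
but never annotated. Annotations come from GAF 2.x and/or NCBI gene2go
dialects; `NOT`-qualified rows are excluded (they assert absence of
function), evidence codes are kept by default (an exclusion list, e.g.
`IEA`, is a build flag — the default is inclusive), annotations to terms
missing from the ontology release are counted and skipped rather than fatal.
Gene identity is normalized to official symbols at build time: numeric gene
ids map through the gene table, synonyms resolve when they point to exactly
one official symbol, and unresolved keys are kept verbatim (and added to the
universe) with a reported count — dropping them silently would bias K for
non-model species with patchy symbol coverage.

**Flat path.** KEGG-style, Reactome-style, DISEASES-channel and DisGeNET
inputs are three-column term–gene tables. Pairs are de-duplicated, genes
outside the species universe are dropped (with a count), and empty terms are
pruned (K = 0 terms are untestable). Disease channels (text mining,
knowledge, experiments) are unioned pairwise with channel provenance
retained. No DAG propagation is applied on the disease side; the flat
channel tables are the annotation source.

**Universe.** The default background is every official symbol the gene
table lists for the taxon — not merely the annotated genes. A user-supplied
background is intersected with this universe, and both N and each term's K
are restricted to it, so a custom background changes the question coherently
rather than only rescaling N.

**Persistence.** Libraries are written as sorted TSV with a format-marker
line and a provenance header (database, taxon, build timestamp, sha256 of
each source file). The universe is stored in the same file under a
pseudo-category so that write→read is the identity on the data model. Apart
from the timestamp line, identical inputs produce byte-identical files;
builds are all-or-nothing per manifest (inputs are validated before anything
is written).

## Defaults that matter

| parameter | default | why |
|---|---|---|
| test | `fisher` | identical to `hypergeom` one-sided; both names accepted |
| adjustment | `BH` | standard FDR control for ORA |
| `min_term_size` | 3 | 1–2-gene terms are untestable and only inflate m |
| `max_term_size` | 5000 | excludes root-level catch-all terms |
| `q_cutoff` | 0.05 | flags/plots only; the full table is always written |
| propagation relations | `is_a`, `part_of` | GO propagation convention |
| evidence filter | none | inclusive by default; opt-in exclusion list |

Query symbols are whitespace-trimmed, case-sensitively matched (case is
meaningful across species), and de-duplicated with a reported count. Ties in
the ranked output are broken by term id ascending, so output bytes are
reproducible run to run.

## The synthetic universe

The fixture generator emulates the *file formats and structure* of a real
species build: a single-root random DAG over four levels with ~10% `part_of`
edges, an alt_id and an obsolete term, 200 genes with NCBI-style numeric
ids, symbols and occasional synonyms, the same annotation truth rendered as
both GAF and gene2go (plus NOT-qualified and off-taxon decoys), and flat
pathway/disease tables. A planted term — a leaf attached directly to the
root, carrying max(30, query_size) member genes that receive no other
decorations — is over-represented in the generated query: a fraction
`effect` (default 0.5) of the 25 query genes is drawn from its members, the
rest uniformly from the universe. Planting the term as a root-child leaf
keeps the signal from being absorbed by intermediate ancestors, which in
real GO data routinely outrank the specific term that drives them.

What the generator does **not** emulate: inter-gene correlation, term-size
distributions of real ontologies (tens of thousands of terms spanning 5
orders of magnitude), annotation bias toward well-studied genes, and
ambiguous symbol collisions across paralogs. Passing tests therefore
demonstrate correctness of the computation and calibration under the model's
own null — not robustness to the dependence structure of real expression
data.

## Problem sizes in the checks

The exhaustive exact-test scan covers every valid table with N ≤ 60
(~635,000 tails) against integer-arithmetic enumeration; adjustment is
checked on 1000 random vectors of length 1–200; propagation on 100 random
DAG fixtures (≤ 15 terms, ≤ 50 genes) against a naive per-gene DFS; null
calibration on 1000 uniform queries against one fixed term of the generated
GO library, compared to the exact attainable level of the discrete test
(markedly below 0.05 — discrete conservatism is expected, not a defect);
planted recovery on 100 end-to-end seeded pipeline runs at generator
defaults. These sizes keep the whole suite in the tens of seconds while
leaving the guarantees exhaustive where exhaustiveness is feasible.

## Known limitations

- No GSEA-style ranked-list statistics, gene permutation, or
  topology-aware pathway scoring; ORA only.
- No KEGG BRITE hierarchy modelling and no Disease Ontology DAG
  propagation (flat channel tables stand in for the disease dimension).
- Symbol resolution cannot disambiguate a synonym shared by multiple
  official symbols; such synonyms are left unresolved by design.
- No network retrieval: the package consumes files already on disk; the
  fixture generator stands in for downloads in tests and examples.
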