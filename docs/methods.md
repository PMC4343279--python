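# Methods

## The enrichment model

The core statistic is the hypergeometric test for over-representation.
A universe of `N` genes contains `M` annotated to a given MeSH term; a
study selects `k` interesting genes of which `x` carry the annotation.
Under the null of annotation-independent selection, `x` follows a
hypergeometric distribution, and the reported p-value is the upper tail
`P(X ≥ x)`. The point mass `C(M,x)·C(N−M,k−x)/C(N,k)` is exposed
separately (`hypergeom_pmf`); testing the tail rather than the point
mass follows universal ORA practice (GOstats and every successor) and
is the single most consequential interpretation choice in the package —
the point mass alone would *reward* extreme depletion as well as
enrichment and is not a test statistic. Probabilities are computed with
log-gamma arithmetic, summed over the tail; when `x` sits at the lower
support bound the tail is returned as exactly 1 rather than a rounded
sum. An independent exhaustive-enumeration oracle (every `C(N,k)` draw,
N ≤ 12) and scipy's survival function back the implementation in tests.

**Universe definition.** `N` counts only genes carrying at least one
link of the requested category and source, and the multiple-testing
family is the set of terms tested within one category per run. Counting
the whole gene complement instead would inflate `N` and every
significance call; restricting per category matches how per-category
results are reported in practice. Annotations are **not** propagated up
the hierarchy: a term counts only its direct links. Hierarchy-aware
counting (each gene also counted for all ancestors of its terms) is a
defensible alternative and a known divergence risk when comparing with
other implementations; it is deliberately not the default because it
couples the test family's dependence structure to the DAG shape.

**Determinism.** Rows are sorted by raw p ascending with ties broken by
term id; reports serialize floats via `repr`, so serialize → parse →
serialize is byte-identical.

## The annotation store

The vocabulary is a multi-parent DAG, not a tree: MeSH headings occur
at several tree positions, so parent–child edges (PCR) form a
poly-hierarchy and a DAG subsumes the tree case. Ancestor–offspring
relations (AOR) are *derived* at build time as the transitive closure
of PCR — storing both independently would create a consistency failure
mode that the derived form makes structurally impossible, and the
closure invariant is checked in tests against a plain BFS-reachability
oracle. Ancestor sets are strict (a term is not its own ancestor).

`select(keys, cols, keytype)` operates on the long-format join of the
term and link relations, exploded over every multi-valued attribute
(qualifiers, synonyms, document ids). Duplicate rows are preserved —
these are relational SELECT semantics — and row order is deterministic
(sorted by the keytype column, then the projected columns). Missing
keys yield empty results; only malformed schema names raise. On disk a
store is a directory of three TSV tables plus a `key=value` manifest;
reload recomputes the closure, and a write–read–write cycle is
byte-identical.

## Building annotations

The literature route counts distinct genes per paper **in the
gene-to-PubMed input alone, before the join**, and drops every paper
above the threshold (default 1000, strict: a 1000-gene paper is kept,
a 1001-gene paper is not). Papers indexed to thousands of genes are
genome-scale reports whose gene lists carry no per-gene specificity;
filtering after the join would leak their terms back in through
aggregate counts. The threshold is applied per input table (per
organism in typical use). Text-mining-derived inputs are accepted only
as precomputed (gene, term) tables; their relevance scoring is external
to this package.

The projection route copies every link of a major-organism gene onto
its reciprocal-best-hit partner, tagging the source `RBBH` and
preserving document ids; a minor gene hit in several major organisms
receives the union, with document sets merged per (gene, term). The
output term set is provably a subset of the input term set.

## Reciprocal best hits

Pairing uses optimal Smith–Waterman local alignment under BLOSUM62 with
affine gaps: a gap of length L costs `open + L·extend`, defaults 11 and
1 (the BLAST-style convention; in Biopython's PairwiseAligner terms,
`open_gap_score=-12, extend_gap_score=-1`). The original sweeps used a
heuristic search engine; only its scoring model is kept, because the
method's substance is the mutual-best-hit rule, not the seeding
heuristics. Matrix and gap defaults are this package's choice — the
upstream parameters were never stated. Best-hit ties break to the
lexicographically smallest subject id so runs are reproducible; the
score matrix is computed once and reused for both directions (the
matrix is symmetric). `min_score` defaults to 0 — keep every
positive-scoring hit — mirroring the extremely permissive E-value
cutoff (50) of the original sweeps; `evalue_proxy` provides a
Karlin–Altschul-style monotone proxy (gapped BLOSUM62 constants
λ=0.267, K=0.041) without re-implementing BLAST statistics.

For the synthetic-proteome recovery study the evaluation uses
`min_score=100`: at length 120, chance local alignments of unrelated
random sequences score ≈40–60 while true ortholog pairs at 2×5%
divergence score ≳400, so the cutoff sits in a wide empty margin.
Threshold-free RBBH on random decoys *will* emit spurious mutual pairs
(any two unrelated sequence sets have some mutual best hits); a score
floor is what a practitioner always applies.

## FDR corrections

All three corrections address the same two-groups model: a fraction π₀
of hypotheses are null with Uniform(0,1) p-values.

* **BH**: `q_i = p_(i)·(m/i)` on the sorted sequence, then a running
  minimum from the largest rank (step-up monotonization), capped at 1.
  The per-rank formula alone is not monotone, and without
  monotonization "adjusted p-values" would not be valid; the step-up
  form reproduces the classic rejection rule exactly. Rejection is
  strict (`adjusted < α`). The product is evaluated as `p·(m/i)`, not
  `(p·m)/i`: the former keeps `q = p` exactly at the top rank and
  avoids spurious strict-inequality flips at round thresholds.
* **Q-value**: π̂₀ times the BH values. π₀ is estimated by Storey's
  recipe: tail fractions `π₀(λ) = #{p>λ}/(m(1−λ))` on λ = 0.05…0.90
  step 0.05, smoothed by a least-squares natural cubic spline with 3
  degrees of freedom (boundary knots at the grid ends, one interior
  knot at the median), read off at λ = 0.90 and clamped to (0, 1].
  Families smaller than 20, or degenerate all-equal vectors, fall back
  to π₀ = 1 (i.e. plain BH), flagged in the estimate's `method_note`.
* **Local FDR**: `π̂₀·f₀(p)/f(p)` with `f₀ ≡ 1` and `f` the Grenander
  estimator — the left derivative of the least concave majorant of the
  empirical CDF, the maximum-likelihood estimate among non-increasing
  densities. Values are clamped to [0, 1] and made monotone in p.
  Spline df, λ grid and the Grenander choice are concrete realizations
  of methods the literature specifies only at a higher level; each sits
  behind its operation contract so it can be swapped.

`choose_method_diagnostics` reports the decile histogram and a KS
distance from uniform, advisory only: BH when the histogram is flat
outside a spike at 0, Q-value/local FDR when the null fraction is
visibly below 1.

## Synthetic data

The generators define the package's study conditions; all are pure
functions of parameters + seed.

* **Vocabulary**: `n_terms` terms in index order, each non-root term
  with one uniformly chosen earlier parent and a ~10% chance of a
  second — a DAG with multi-parent nodes by construction. Categories
  are drawn from the requested subset of the 16 codes.
* **Annotations**: independent Bernoulli(density) links, default
  density 0.05 over 2000 genes × 200 terms, with 1–3 simulated
  document ids each. Real literature annotation is heavy-tailed and
  correlated across related terms; these fixtures are not, so passing
  recovery tests demonstrates the machinery, not robustness to real
  annotation structure.
* **Studies**: each gene selected with base probability 0.1, its odds
  multiplied by `planted_effect` (default 8 in recovery studies) if
  annotated to the planted term. Effect 1 is the null design. Pipeline
  recovery fixtures use a single-category vocabulary so the tested
  family is the full term set, matching the per-category correction
  family.
* **p-value mixtures**: Uniform(0,1) nulls, Beta(shape, 1) alternatives
  (default shape 0.1), π₀ = 0.8 in control studies — Beta(·,1) has a
  closed-form CDF, making oracle reasoning easy; labels are returned
  for FDP scoring.
* **Proteomes**: per pair, a random length-120 ancestor is mutated
  independently on both branches at 5% per site; 20 pairs plus 20
  random decoys per side. Real proteins have domain structure and
  biased composition; these do not, which makes score separation
  cleaner than in real data.

Simulation sizes throughout (200 FDR replicates of m=1000, 100 recovery
replicates at 2000×200, 10 proteome seeds, DAGs to 100 nodes, exhaustive
enumeration to N=12) are chosen so the full suite and the acceptance
script each complete in about a minute on one CPU while keeping
Monte-Carlo standard errors well inside the asserted margins.

## Literature organization

Document records are the flattened (document × gene) set behind each
significant term, deduplicated across annotation sources. Filing is
`root/<key>/<pubmed_id>.<ext>` keyed by gene, term or document id;
re-runs are idempotent, and a failing fetch is recorded as `missing` in
the manifest without aborting the run. Retrieval is always an injected
callable: the core never opens a network connection, which is what
makes the component testable and deployment-agnostic.

## Known limitations

* Only integer (Entrez-style) gene ids are accepted; identifier
  conversion is out of scope.
* Annotations are not hierarchy-propagated before testing (see above).
* The RBBH engine is exact but quadratic; it is meant for desk-scale
  sets, not cluster sweeps.
* π₀ estimation is unreliable for small families (hence the hard
  fallback at m < 20) and the local FDR inherits the Grenander
  estimator's spiking near p = 0 for tiny samples.
* `select` materializes the exploded join in memory; stores with
  millions of links would need a real embedded database behind the same
  contract.
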