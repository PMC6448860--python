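# Methods

## Pipeline model and assumptions

The pipeline treats a disease as a set of risk genes and a biological
process as a set of annotated genes, and reduces every relationship —
catalog↔term, term↔term, drug↔term, DE-genes↔catalog — to a cumulative
hypergeometric overlap test. This assumes genes are exchangeable draws
from a fixed universe: no annotation propagation up the GO DAG (the GMT
is taken literally), no gene-length or expression bias, no direction of
drug action (an antagonist and an agonist of the same target are
equivalent). Those are the standard simplifications of overlap-based
enrichment and the price of needing nothing beyond set membership.

Two different universes are deliberate, not accidental:

* term enrichment and term–term edges use the **whole-gene universe**
  (by default the union of the level-filtered annotation's genes and
  the catalog, overridable by an explicit universe file, since "the
  whole genome" is not a number two annotation releases agree on);
* drug–term edges use the **risk catalog itself** as the universe, with
  the term's gene set restricted to risk genes. This is the only
  internally consistent choice: the drug's targets are already
  restricted to risk genes, so an unrestricted term size K could exceed
  the universe M and the distribution would be undefined.

## Hypergeometric tail direction

The cumulative form Σ_{i=0}^{x} is a *lower* tail and measures
depletion; every scientific use here is enrichment, so the default is
the upper tail P(X ≥ x). The literal lower-tail sum remains available
as `tail="printed-lower"` for auditing, and the identity
`upper(x) + printed-lower(x−1) = 1` is enforced by tests. Tails are
computed by `scipy.stats.hypergeom` survival/cdf functions (log-space
internally); BH adjustment by `statsmodels`, with an independent
step-up reimplementation used as the test oracle. BH runs within each
test family separately (term enrichment; all term pairs; all drug–term
pairs), matching per-network FDR semantics.

## GO level

"Level 3" means three `is_a` edges from the namespace root along the
*shortest* path (root = 0) — the commonest convention in GO-level
tools; a longest-path mode exists because the convention is not
universal (`--level-mode longest`). Only `is_a` edges are used;
`part_of` and other relations are ignored (documented limitation), and
obsolete terms are dropped at parse time. Non-BP namespaces are
excluded by default.

## Network construction and topology

All C(n,2) unordered pairs of significant terms are tested once; edges
keep BH q < 0.05; isolated significant terms remain nodes, so node
count equals significant-term count. Betweenness is the standard
fractional definition Σ σ_st(v)/σ_st, unnormalized, disconnected pairs
contributing zero — what igraph and Cytoscape's NetworkAnalyzer
compute; a `raw-counts` mode preserves the literal "number of shortest
paths through v" reading. Node and edge listings are sorted
lexicographically, and undirected edges serialize once with ordered
endpoints, so output files are byte-stable.

Zero-degree drugs and terms are dropped from the bipartite network but
reported in a side list — the network describes connected entities
only. The degree distribution is summarized by ordinary least squares
of log10(count) on log10(degree) over non-empty bins, reported as
`f(k) = a·k^b` with an r² on the log-log scale. OLS-on-binned-counts is
the classical reporting convention this mirrors; it is *not* the
statistically efficient estimator of a power-law exponent
(maximum-likelihood α̂ with tail cutoff is), and the exponent should be
read descriptively.

## Association score and permutation null

`S = −log10 Σ_k P_drug,k · P_disease,k` over the terms present in both
profiles. The drug profile holds the raw drug–term p on each of the
drug's network edges; the disease profile the raw enrichment p on every
significant term. p-values are floored at 1e-300 before products. Two
readings of the score's summation domain exist (a sum over all shared
terms versus the single most significant term); the sum is the default
because the formula is a sum, and a single-term mode is a one-line
restriction callers can apply to their profiles.

The null shuffles the *disease* profile's p-values across its full term
vector while the drug's adjacency stays fixed, then recomputes the
shared-domain sum. Under this scheme a drug scores high only when its
terms are among the disease's *most* significant ones — specificity,
not mere overlap. A `perm_domain="shared"` variant shuffles within the
shared set only; both are defensible readings of "randomly ranking the
GO functions" and neither is asserted as uniquely correct. Monte-Carlo
uses the sample (n−1) standard deviation of 10,000 shuffles; exact mode
enumerates all permutations (domain ≤ 8) with population moments and is
the sampler's oracle. A constant disease profile makes every shuffle
identical; Z is then undefined (flagged, never an exception), and such
drugs are never candidates. Candidates require strictly Z > 1.96.

## Expression validation

Welch's unequal-variance t-test per gene (pooled-variance mode behind a
flag), two-sided fold-change filter: significant ⇔ p < 0.05 and FC ≥ 2
or ≤ 0.5. Intensities are declared `log2` (beadchip convention) or
`linear`, never guessed: log2 data use FC = 2^(mean difference), a
geometric-mean ratio; linear data the arithmetic-mean ratio. The two
conventions agree exactly only at zero within-group variance — tests
assert closeness, not identity. Raw p-values are thresholded without
multiple-testing correction, matching the validation contract this
stage implements; genes with zero variance in both groups get an
undefined p and are flagged non-significant.

## Synthetic worlds

The generator emulates the full input suite under one seeded
`numpy.random.default_rng` stream (identical seed ⇒ byte-identical
files). Defaults are the validated study conditions:

| parameter | default | why |
|---|---|---|
| n_genes | 2000 | large enough for stable hypergeometric tails, small enough for fast tests |
| n_terms / dag_levels | 150 / 5 | bulk of terms at level 3 so the level filter is non-trivial |
| term_size_range | 10–50 | typical leaf-ish GO BP set sizes |
| terms_per_module / module_pool_size / module_fraction | 4 / 40 / 0.6 | sibling terms share a gene pool, giving the term network real edges |
| n_disease_genes / n_enriched_terms / enrichment_fraction | 120 / 8 / 0.6 | catalog scaled to ~half the motivating study's 258 genes; 60% planted in whole modules, allocated round-robin so each term is individually enriched |
| n_true_drugs / n_null_drugs / targets_per_drug / overlap fraction | 10 / 20 / 6 / 0.6 | true drugs concentrate signal targets in ONE planted term (drugs act within a function); null drugs draw uniformly |
| n_case / n_control | 13 / 12 | the validation dataset's group sizes |
| n_de_genes / log2fc_effect / noise_sd | 100 / log2(2.5) / 0.4 | 2.5-fold planted shifts against realistic log2 microarray noise |

What the generator does **not** emulate: realistic GO DAG topology,
annotation propagation, correlated expression, probe-level artifacts,
polypharmacology structure, or any correlation between planted DE genes
and the catalog. Passing recovery tests therefore demonstrates the
machinery is correct and calibrated under exchangeable-gene conditions;
it does not certify performance on real catalogs, where annotation bias
and gene correlation violate the hypergeometric assumptions.

## Numerical and degenerate-input choices

* Hypergeometric inputs validate 0 ≤ x within [max(0,K+N−M), min(K,N)]
  and name the violated bound.
* Empty query/universe, cyclic ontologies, unknown terms, malformed
  files raise typed errors (CLI exit 2 for usage/config, 1 for data).
* Enrichment ties sort by (p, term id); all listings lexicographic.
* Terms with fewer than `min_query_genes` (default 5) overlapping
  catalog genes are not tested and not counted in the BH family.
* Drug–term tests with K = 0 are skipped, not counted as p = 1.
* Power-law fit requires ≥ 2 distinct non-empty degree bins.

## Problem sizes used in the test suite

The recovery and calibration suites run on the default 2,000-gene world
(five seeds), 200 null drugs at 2,000 permutations each, exhaustive
hypergeometric enumeration to M = 12, brute-force network
reconstruction to 40 terms and 15 drugs × 20 terms, and a 5,000-gene
world for the expression stage — sizes chosen so the complete suite
runs in well under a minute while every check remains non-trivial.

## Known limitations

* The GO level of a term depends on the ontology release; results
  filtered at level 3 are version-dependent by construction.
* OLS power-law fitting is descriptive (see above).
* The association Z is not corrected across drugs; the candidate list
  is a screen, not a confirmatory test.
* Gene identifiers are assumed to be symbols; mixed namespaces are the
  caller's responsibility (normalization is trim + upper-case only).
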