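# Methods

This note records the models, conventions and synthetic study
conditions behind gosemtk, and the design choices made where the
definitions in the literature leave room.

## Ontology model

Each GO namespace (BP, MF, CC) is a single-rooted DAG over non-obsolete
terms. Edges are stored child → parent — from a term toward more
general terms — and only `is_a` and `part_of` relationships are kept,
so "ancestors of *t*" are exactly the nodes reachable from *t*.
Obsolete terms are dropped from the graphs at parse time but remembered
so annotations pointing at them can be counted; `alt_id` accessions are
remapped to their canonical term. Cycles or multiple roots after
relation filtering are fatal: GO namespaces are single-rooted, and a
multi-rooted graph would break the `P(root) = 1` anchor below.

Ancestor sets used in all semantic calculations are **reflexive**
(contain the term itself). This is what makes `Resnik(t,t) = IC(t)` and
`Lin(t,t) = 1`, and it is applied uniformly across the shared-information
algorithms and the Jaccard-family closures. Topology statistics are the
exception: mean ancestor counts use proper (non-reflexive) ancestors,
since they are compared against `log n` as a tree-likeness gauge. The
mean branching factor is `|E|/|V|`; with each edge counted once, the
mean parents-per-node and mean children-per-node coincide, which
resolves the ambiguity in "node degree".

## Annotation counting

The occurrence-counting unit is the deduplicated (gene, term) pair, not
the raw annotation line: GAF files repeat an association across
references and evidence codes, and raw-line counting would inflate term
probabilities in an artifact-dependent way. Electronically inferred
(IEA) annotations are included by default; records with a NOT qualifier
are excluded by default. Both are configurable.

Cumulative counts propagate by record, not by summing child counts up
edges: each record contributes exactly once to every reflexive ancestor
of its term. Edge-summation would double-count through DAG diamonds and
break `P(root) = 1`. Terms with zero cumulative count are *unscored*:
they carry no probability or IC, and any similarity query touching them
raises an error rather than silently returning 0.

The default logarithm base is natural; the ratio-form measures (Lin,
SimUI/GIC/DIC/UIC) are base-invariant, and worked examples that quote
Resnik-scale values state bits explicitly.

## Shared information

All five algorithms operate on the common-ancestor set
`CA(t1,t2) = Anc(t1) ∩ Anc(t2)` and return `IC(t)` when `t1 = t2`.

* **CASI** — mean IC over CA.
* **MICA** — max IC over CA (`−log` of the minimum-subsumer probability).
* **GraSM / A-GraSM** — mean IC over the disjunctive common ancestors
  (DCA). The published prose fixes neither the processing order nor
  whether path counts are compared per input term or summed, so the
  following deterministic reading is pinned here: candidates are
  processed in decreasing IC order (ties broken lexicographically by
  term id); the selected set is seeded with the MICA; a candidate *a*
  is admitted iff `np(a) ≥ np(s)` for every already-selected *s*, where
  `np(a) = paths(t1→a) + paths(t2→a)` counts directed child→parent
  paths. A-GraSM replaces ≥ with a strict >. This reading reproduces
  the documented qualitative behaviour (the GraSM DCA is large and
  includes the root; A-GraSM is a strict tightening) and is pinned by
  exact tree-limit identities: on any tree every `np` is 2, so GraSM
  degenerates to CASI and A-GraSM to MICA. Path counts are memoized
  dynamic programming per query; no O(n²) all-pairs path map is
  precomputed.
* **Semantic frontier (SF)** — mean IC over the common ancestors that
  have an incoming edge from either input's exclusive ancestor region
  `(Anc(t1) ∪ Anc(t2)) − CA`; a linear-time stand-in for exclusively
  inherited common ancestors, and also MICA on trees.

Useful bounds that hold by construction and are property-tested: every
method is symmetric, non-negative, bounded above by MICA, which is
itself bounded by `min(IC(t1), IC(t2))`.

## Term and gene similarity

Jiang-Conrath is kept in its raw affine form `1 − (IC1 + IC2 − 2·SI)`;
it can be negative or exceed 1 and is deliberately not clamped.
Consumers that need [0,1] (e.g. similarity-to-distance conversion for
clustering) rescale explicitly. Lin's 0/0 at the root — and more
generally between two zero-IC terms, which a degenerate corpus can
produce — is defined as 1: such terms are informationally
indistinguishable.

Precomputed term-similarity matrices are restricted to corpus-annotated
terms and store the strict upper triangle plus diagonal
(`n(n−1)/2 + n` entries). The file format is a long-form TSV
(`term1 term2 value`) with a `#` metadata header carrying the SI/term-
similarity names, log base, namespace and a corpus hash, so a matrix
cannot be silently combined with the wrong ontology or corpus.

A gene's profile is its annotated term set plus the union of those
terms' reflexive ancestor closures. The Jaccard-family measures are
written for term arguments but act on these gene-level closures.
Best-match average (the default aggregator) is the symmetric mean of
each gene's per-term best match against the other gene's terms. Genes
without annotations in a namespace are undefined there; callers drop
such pairs and count them.

## Statistical harness

* **Bootstrap** distributions use the seed schedule `base seed +
  replicate index`, so any replicate is individually reproducible.
  Degenerate samples (constant columns, single-class draws) are redrawn
  within the replicate and counted.
* **ROC/AUC** uses the rank-based estimator, equal to the Mann–Whitney
  pair-comparison statistic with ties counted half.
* **Variation of information** is computed in nats; the normalized form
  divides by `log(item count)`, and `1 − normalized VI` is the
  similarity reported for clustering recovery.
* **Ward clustering** follows scipy's Lance–Williams recursion on a
  precomputed dissimilarity matrix (the Ward.D2-style update). On
  non-Euclidean dissimilarities the recursion can emit slightly
  negative or non-monotone merge heights; since only the merge order
  matters for a maxclust cut, heights are monotonized before cutting.
  Unbounded similarities (Resnik, JC) must be min-max rescaled per
  measure before `1 − similarity` distances; the bounded measures are
  used as-is.
* **Ranking** is competition ("exhausted") ranking over statistical
  ties: methods are sorted by mean, a method joins the current tie
  chain when Welch's t-test against the chain leader cannot reject
  equal means at α = 0.05, tied methods share the chain's best rank and
  the next chain starts past the block (1, 1, 3, …). A zero-variance
  pair falls back to exact mean comparison, logged.
* **Factor influence** is a sequential (type-I) ANOVA of mean
  performance on one-hot categorical factors (ontology, term
  similarity, shared information), reported as `−log10 p`. Aliased
  (identical) factor columns and single-level factors are rejected.
* **Threshold classifiers** scan all observed score values, predict
  positive at `score ≥ threshold`, and keep the smallest F-score-
  maximizing threshold. A consequence worth knowing: on continuous
  separable scores the chosen threshold sits exactly on the training
  minimum of the positive class, so the global minimum positive always
  costs one held-out error; exact-zero cross-validation error is only
  attainable with discrete score levels.
* **Majority voting** predicts positive only on a strict majority; an
  even split is negative (the conservative reading).
* **Cross-validation** folds are simple random (unstratified) but
  seeded; a training split missing a class triggers one reshuffle with
  an incremented seed, then fails.

## Synthetic study conditions

The fixture generators are pure functions of their parameters (seed
included); regeneration is byte-identical. The toolkit-wide default
seed is 1729. Effect sizes below were chosen once as plausible
planted-structure regimes and are documented constants.

* `toy1` / `toy2` — seven-term diamond DAG and four-term tree with
  four-record corpora; small enough that every IC, path count, DCA set
  and similarity value is hand-checkable, which is how the worked
  examples in the tests were derived.
* `random_dag` / `random_tree` — growth processes that attach each new
  term to existing terms, so acyclicity and single-rootedness hold by
  construction. Used as the substrate for the oracle-equivalence and
  invariant property suites (typically ≤ 30 terms, 50–100 seeds — sizes
  at which exhaustive brute-force oracles are still exact).
* `ppi_signal` — 8 modules × 8 genes on an ~80-term DAG; within-module
  pairs are interaction positives. Gene profiles share a module anchor
  term; reference tables carry matched signal (reciprocal bit scores at
  0.55–0.95 of the self score for positives vs 0.02–0.25 otherwise,
  module-specific Pfam-style domains plus a ubiquitous housekeeping
  domain, expression = module latent profile + N(0, 0.5) over 20
  conditions). 224 positive and 224 negative pairs.
* `pathways` — 3 pathways × 10 genes, each pathway owning an ontology
  branch whose sub-terms its genes annotate; used for Ward/VI recovery.
* `multiview` — 600 pairs, three independent latent views v_BP, v_MF,
  v_CC ~ N(0,1); the label is the majority of view signs, so no single
  namespace determines the class. Each namespace emits 3 score columns
  `v_ns + η_ns + ε` with shared within-namespace noise η ~ N(0, 0.4)
  and tiny jitter ε ~ N(0, 0.005): columns inside a namespace carry the
  same partial information (so within-namespace voting cannot beat its
  best member beyond noise), while voting across namespaces
  approximates the majority-of-views Bayes rule and beats every single
  measure.

What passing on these fixtures does and does not show: the planted
scenarios verify that the pipeline recovers structure it is guaranteed
to contain and that chance baselines stay flat — they say nothing about
effect sizes in real GOA/BLAST/Reactome data, where annotation depth is
uneven, namespaces are correlated, and reference similarities are far
noisier. Real-data conclusions require running the same harness on real
tables, which the TSV interfaces accept unchanged.

## Known limitations

* Only `is_a` and `part_of` edges; no `regulates`/`has_part`, no OWL.
* No GPAD/GPI annotation formats; no taxon filtering.
* The GraSM DCA admission rule is one consistent reading of an
  under-specified published procedure (see above); alternative readings
  (per-input path comparison, non-sequential admission) would differ on
  DAGs while agreeing on trees.
* BLAST/HMMER/expression preprocessing is out of scope; reference
  scores arrive as tables, and upstream e-value cut-offs are the table
  producer's concern.
* The bootstrap treats table rows as exchangeable; paired-gene
  dependence structure is not modeled.
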