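# Methods

## The knowledge-network model

A biomedical knowledge network is a directed multigraph `G = (V, E, C, S)`.
Concepts carry a stable id, a label, and exactly one owning ontology
(`Φ: V → O`, total). Edges carry a relation type (`Ψ: E → R`), a confidence
`C(e) ∈ [0, 1]` and a significance `S(e) ∈ [0, 1]`. An edge is an
intra-relationship iff its endpoints share an ontology, otherwise an
inter-relationship; the two classes partition `E`.

Key modelling commitments:

- **Directionality.** All traversal is forward over stored edges. Ontology
  hierarchies that should be walkable in both directions are materialized as
  two separate typed edges (e.g. `father_to_son` / `son_to_father`), which
  loaders can do from a declared inverse map. This is the only reading under
  which the bundled worked example reproduces its expansion sets: the
  anchor's intra set contains its children but not the anchor itself.
- **Parallel edges.** Two concepts may be linked by several edges of
  different relation types; an exact duplicate `(source, target, rel)` is a
  data error and rejected.
- **Defaults.** Structured-source (ontology) edges default to confidence 1.0
  and significance 1.0. The significance default is a package choice — the
  convention only fixes the confidence default — kept equal to it for
  symmetry and configurable at load time.
- Self-loops and out-of-range weights are rejected at construction;
  `BMKN.validate()` re-checks all invariants and reports violations instead
  of raising, for use on assembled or deserialized networks.

## The expansion recursion

Relatedness around an anchor concept is the indexed family `iO_t^j` — per
ontology `t`, the concepts collected after `j` intra steps and `i` inter
steps — defined by the three-branch recursion (diagonal union; intra step on
`i < j`; inter steps into `t` from every other ontology's previous diagonal
on `i > j`), grounded at the initial sets `O_t^0`: forward intra neighbors
of the anchor for its own ontology, forward inter neighbors restricted to
`t` for every other one. This grounding is the direct n-ontology
generalization of the printed two-ontology definitions. The anchor is
excluded from every set and from the reported relatedness network, matching
every printed identity.

Numerical/algorithmic choices:

- **Memoization.** Each cell is a pure function of `(i, j, t)` given the
  network and the mask, so `ExpansionState` caches cells. Purity is enforced
  by construction (no cell is mutated after being filled) and checked
  against a deliberately naive uncached re-evaluation in the test suite —
  an independent second implementation, not a code path of the engine.
- **Primitive operators return neighbors only.** `intra_step`/`inter_step`
  return the one-step forward neighbor set *without* unioning their input;
  the recursion composes "∪ previous" explicitly, mirroring how every
  printed identity is written.
- **Step semantics.** The initial set is already one forward step from the
  anchor, so in a network without inter edges the cell `(i, j)` of the
  anchor's ontology equals the forward intra ball of radius `j + 1`; with no
  intra edges the step-`i` diagonals cover forward inter-walks of length
  `≤ i + 1`. Both limits are asserted against breadth-first reachability.
- **First-collection indices.** RN nodes are annotated with the first cell
  containing them, scanning cells in order of `i + j` (then `i`); ties are
  therefore resolved toward fewer total steps.
- The diagonal profile reports, for step-count selection, the diagonal sets
  per step and the first step at which nothing grew (the fixpoint); an
  anchor with empty initial sets is at its fixpoint at step 0.

## Pruning

- **Interesting set.** `F(i) = iO_t^i − 0O_t^i` removes everything reachable
  by intra expansion alone. `F(0) = ∅` and `F(i) ⊆ iO_t^i` always; `F` is
  empty at every step in a network without inter edges.
- **Link masks.** A mask `R(t, c, s)` admits an edge of its relation type
  iff `t = 1` and confidence `> c` and significance `> s` — comparisons are
  strict, so boundary equality blocks; with `t = 0` the thresholds are
  irrelevant. A mask set resolves a relation type by first matching typed
  entry, then the wildcard (`rest`/`all`); unmatched types pass. Masks apply
  at traversal time so one network serves many masked queries; whole-graph
  pruning (`apply_masks`) keeps exactly the passing edges and is provably
  equivalent, which the suite asserts cell-by-cell.
- **Monotonicity, and its limit.** Tightening a mask (raising a threshold or
  flipping an include flag to 0) never enlarges any cell: every cell is a
  monotone function of the traversable edge set. The same is *not* true of
  `F(i)` in general — removing an edge can shrink the intra-only subtrahend
  `0O_t^i` and thereby move a concept *into* `F(i)`. The guarantee that
  survives, and that the suite asserts, is for the anchor's own ontology
  under tightenings confined to cross-ontology relation types, where the
  subtrahend uses no inter edge. A minimal counterexample for the general
  claim is kept as a regression test.
- **Hub exclusion** removes concepts whose degree (in + out, under a chosen
  relation class) exceeds a cutoff, with their incident edges — emulating
  the removal of gene-product properties linked to very many genes. There is
  deliberately no default cutoff: callers pass either `max_degree` or a
  `top_percentile` of the positive-degree distribution.

## Corpus weighting

Confidence of a co-occurring concept pair `(u, v)` over an `N`-document
corpus: `tf = n(u, v)` (documents containing both — a pair counts at most
once per document, so document frequency equals `n`), smoothed
`idf = log((N + 1)/(n + 1)) + 1`, and `confidence = tf·idf / max tf·idf`.
The `+1` terms keep single-document corpora positive and floor idf at 1;
max-normalization maps into `(0, 1]` with the strongest pair at exactly 1.
The choice of a *pair-level* TF-IDF (rather than per-term) is this module's
main interpretive decision and is isolated behind `tfidf_confidence`.
Significance is the mean impact factor of the pair's supporting documents,
normalized by the maximum such mean — bounded in `(0, 1]` and invariant
under rescaling all impact factors; if every impact factor is zero the
computation refuses and callers fall back to default weights. Extraction
emits both directed edges per surviving cross-ontology pair (same-ontology
pairs are skipped by default); `min_count` defaults to 1.

## Evaluation harnesses

- *Differential-diagnosis design*: candidates are `F(steps)` restricted to
  the anchor's ontology (steps defaults to 2, the convention used
  throughout); the baseline is the intra-only ball `0O^radius` with the same
  radius. Recall = `100·|candidates ∩ reference| / |reference|`, reported to
  one decimal.
- *Disease-pair design*: each `F(steps)` member forms one (anchor, partner)
  pair; the hit ratio is the confirmed fraction, reported to two decimals.
  The random baseline draws the same number of distinct partners uniformly
  without replacement from the anchor's ontology, seeded; its expected hit
  ratio is `|confirmations| / (|universe| − 1)`, which the suite checks by
  Monte-Carlo within three standard errors.
- *Mask sweep*: per mask set, the edges kept and the mean `F(steps)` size
  over the anchor list, as a percentage of the unmasked mean (the no-mask
  row defines 100 %).

## Synthetic data

- **Worked-example fixture** (`fig3_fixture`): the minimal two-ontology
  graph satisfying all nine printed expansion identities and the
  Lupus → Painful Swollen Joint → Joint Swelling → Rheumatoid Arthritis
  chain. Each identity was verified by hand-evaluating the recursion on the
  edge list before the fixture was adopted as an oracle; an engine change
  that breaks one indicates an engine bug, not a fixture bug.
- **Random networks**: per ontology, a rooted random tree (capacity-limited
  branching, edges directed parent to child — an "is-a"-like hierarchy)
  plus extra intra edges at `intra_extra_rate` per concept, and directed
  cross-ontology links with Bernoulli probability `inter_rate` per ordered
  pair. Weights are drawn uniformly from configurable ranges (degenerate at
  1.0 by default). Defaults — 3 ontologies, 15 concepts each, branching 3,
  `intra_extra_rate` 0.1, `inter_rate` 0.02 — give sparse hierarchies with
  a handful of cross links, small enough for exhaustive oracle comparison.
- **Planted ground truth**: a two-ontology disease/mediator network where
  each anchor (an internal tree node) is wired to `n_planted` diseases at
  least three forward intra steps away through one dedicated fresh mediator
  each (anchor → mediator → partner), so the partners are discoverable
  exactly by cross-ontology expansion and provably absent from the radius-2
  intra ball. Reference lists add `n_near` (default 1) intra-ball diseases
  so the intra-only baseline is not trivially zero and the method/baseline
  comparison is informative.
- **Toy corpora**: 2–4 uniformly drawn concepts per document, a boosted pair
  injected with probability `pair_bias`, impact factors log-normal
  (μ = 1.0, σ = 0.5; right-skewed, like journal impact factors). All
  generators are pure functions of their configuration and seed.

What the synthetic conditions do *not* emulate: real ontology scale and
degree distributions (DO/GO-sized hierarchies, heavy-tailed gene-product
hubs), annotation noise in literature links, and curated inter-relationship
quality. Passing tests therefore certify the inference and pruning
machinery, not effect sizes on real data; the planted-recovery margins are
properties of the generator's conditions.

## Problem sizes

The suite and the acceptance script use networks of 10–36 concepts for
oracle comparisons (every cell up to `i = j = 4`, 100 networks in the
suite, 30 in the script), 50 concepts for planted-recovery runs over
20 seeds, and corpora of 50–80 documents — sizes at which the naive
uncached oracle remains exhaustive and every identity can be checked
set-for-set.

## Known limitations

- Confidence/significance are filters (mask thresholds), never propagated
  along paths; no path-probability semantics.
- No subsumption reasoning: `is_a` is traversed like any other edge type.
- Concept ids are opaque, case-sensitive strings; CURIE normalization and
  ontology alignment are out of scope.
- The OBO reader honors `[Term]`, `id`, `name`, `is_a`, `relationship`,
  `is_obsolete` only — sufficient for hierarchy-plus-typed-links inputs.
- In non-anchor ontologies `F(i)` has no mask-monotonicity guarantee (see
  above); sweeps interpreting per-mask candidate counts should anchor in
  the ontology of interest.
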