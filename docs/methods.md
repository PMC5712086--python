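# Methods

## Setting

Two ontologies `O1`, `O2` are given as told class hierarchies: atomic
subsumption edges (child, parent), equivalence pairs, and optional
disjointness pairs. A *mapping* is a 4-tuple ⟨e, e′, r, c⟩ with e ∈ O1,
e′ ∈ O2, r ∈ {⊑, ⊒, ≡} and confidence c ∈ (0, 1]; an *alignment* is a set
of mappings, typically one matching system's output. Mapping identity is
the (source, target, relation) triple — confidence is carried through I/O
and reports but never enters set intersection or voting, since two systems
proposing the same correspondence at different confidence agree on the
correspondence. Cross-ontology orientation is always preserved: the source
stays in `O1` and subsumption direction lives on the relation, so ⟨a ⊒ b⟩
and "b ⊑ a" are the same canonical object.

## Entailment by structural closure

The aligned ontology `O^M = O1 ∪ O2 ∪ M` is represented as one directed
graph: told subsumption edges from both hierarchies, plus one edge per ⊑/⊒
mapping and a pair of opposite edges per ≡ mapping or told equivalence.
Strongly connected components are contracted (this subsumes union–find
over equivalence pairs and also absorbs any subsumption cycle), and
`O^M ⊨ x ⊑ y` is answered as reachability of y's component from x's;
`x ≡ y` holds iff the two classes share a component. Reachability is
memoized per queried source component rather than materialized as a full
transitive-closure matrix, because an evaluation touches only the mapped
pairs — a sparse subset of all class pairs.

Over taxonomies with no complex axioms this computes exactly the atomic
subsumption entailments a DL reasoner would return. That is the regime the
disease/phenotype hierarchies are in (no explicit or implicit
disjointness, hence every aligned ontology coherent); ontologies whose
semantics lean on existential restrictions or logical definitions would
need a reasoner behind the same `entails` interface, and the structural
index makes no attempt to recover those entailments. Unknown identifiers
in queries are reported as not entailed, with a one-time warning.

Coherence: a class is unsatisfiable iff its reachable component set
contains both members of a disjointness pair (lifted to components). The
check reports the unsatisfiable classes and one witness pair each. Metric
functions still run on an incoherent aligned ontology but the report
carries the incoherence note prominently; repair is deliberately out of
scope — the toolkit surfaces the problem rather than silently fixing it.

## Consensus voting

Votes are counted per (source, target) entity pair and per system
*family*; a family casts at most one vote per pair regardless of how many
of its variants proposed it. Within a family, an ≡ proposal absorbs
subsumption proposals for the pair; a family proposing both ⊑ and ⊒
without ≡ is resolved to ≡ (logged as a conflict) — the
equivalence-prevails rule applied to its own variants. Across families,
⊑ and ⊒ on the same pair remain distinct directed proposals, each with its
own vote count, but the moment any family proposes ≡ the pair resolves to
a single equivalence whose count is the number of families that proposed
anything for it. Whether a published size curve treated converse
subsumption proposals as one pair or two is not decidable from the outside;
this package's choice (distinct directed proposals, shared pair for
≡-precedence) is documented here rather than claimed canonical.

Consensus confidence is the vote fraction (votes ÷ contributing families):
order-independent and informative. An `equivalence_only` flag restricts
voting to ≡ mappings, reproducing the alternative equivalence-only counts.
The vote-threshold sweep is non-increasing by construction, and
`consensus(v+1) ⊆ consensus(v)` as pair sets.

## Standard vs semantic scores

Standard P/R/F intersect on exact triples. Semantic precision replaces
membership with entailment by the reference-aligned ontology; semantic
recall, symmetrically, with entailment by the system-aligned ontology.
Before semantic scoring, every ≡ mapping is split into its two directed
subsumptions and the split sets are used for **both numerator and
denominator** (the symmetric choice keeps both fractions in [0, 1] and
gives an ≡ mapping half credit when only one direction is derivable).

One consequence worth stating: with split denominators an ≡ false positive
weighs two units while a ⊑ true positive weighs one, so on alignments that
mix relations the semantic precision can sit a hair below the *unsplit*
standard precision. The dominance law that does hold — and that the
property tests assert — is against the standard scores computed over the
same split sets, where explicit membership implies entailment mapping by
mapping. For ≡-only alignments the two baselines coincide.

Edge cases: empty system alignment ⇒ precision reported as 0 with an
explicit "undefined" note (batch runs over systems that failed a task must
not abort); empty reference ⇒ error, recall has no denominator. Metrics
are kept at full precision internally and printed at two decimals,
half-up. Against a baseline reference (precise but very incomplete) only
semantic recall is reported; precision against an incomplete reference
penalizes correct novel mappings and is suppressed as not applicable.

## Unique mappings and contributions

A mapping of system S is *unique* when (a) no other participating system
proposed the same triple explicitly — all individual systems count,
including same-family variants, with a `family_exclusive` flag for the
sibling-tolerant reading — and (b) the vote-2 consensus aligned ontology
does not entail it. By default only ≡ mappings are pooled, because
subsumption-oriented systems otherwise flood the pool with derivable
near-tautologies. A strict relation match is the default for (a); a
`relation_loose` flag lets an ≡ proposal elsewhere block a ⊑ on the same
pair.

Up to `cap` (default 30) unique mappings per system are sampled uniformly
without replacement (seeded, deterministic) into a TSV review sheet with
label columns and an empty verdict column; verdicts (`correct` /
`incorrect`) are read back and precision is estimated from the verdicts
present. Raw counts are stored; nothing is back-derived from rounded
percentages. Contributions follow

    PC_i = |U_i|·P_i / Σ_j |U_j|,   NC_i = |U_i|·(1−P_i) / Σ_j |U_j|

and satisfy Σ_i (PC_i + NC_i) = 1 identically; the report's `Total` row
carries the pooled count, count-weighted mean precision, and the summed
contributions.

## Interactive oracle

The oracle holds a reference alignment as ground truth. Each *first* query
about a mapping is answered truthfully and then flipped independently with
probability `error_rate`; the answer is cached so repeated queries are
consistent (a human expert does not waver), while every call increments
the request counter — the cost metric. Membership is judged on the
canonical triple by default, with a relation-insensitive option. The error
model is independent symmetric flips only; correlated or biased expert
error is out of scope. `gain_report` pairs the F-measure delta between a
before/after evaluation with the requests spent.

## Synthetic fixtures

The generator emulates the shapes of a real track at desk scale:

* **Hierarchies** — multi-rooted DAGs built root-down with level sizes
  proportional to `branching^level` (default branching 2, depth 6,
  300 classes per side; a deliberate ~40× linear scale-down from the
  10⁴-class track ontologies, keeping depth realistic). 15% of non-root
  nodes get a second parent (multiple inheritance). The second ontology
  mirrors the first's structure with fresh identifiers, then 10% of its
  edges are rewired within-level, so the two sides correspond without
  being isomorphic.
* **Truth alignment** — 80 mappings between structurally corresponding
  nodes; 75% ≡, the rest ⊑ toward an ancestor's counterpart, mirroring
  curated sets that mix equivalence with (harder) subsumption.
* **Systems** — the default roster is eleven simulated matchers in seven
  families (two families submitting three variants each), with
  precision/recall targets spanning (0.70–0.97, 0.40–0.90), the spread a
  real campaign shows. Each truth mapping is recalled with probability
  `recall_target`; false mappings are added to meet `precision_target`,
  drawn with probability `confusability` (default 0.6) as *near-misses* —
  a true target replaced by one of its siblings or parents. Structured
  near-misses are what make semantic and standard scores diverge, the
  phenomenon the semantic measures exist for; purely random noise would
  never be entailed and the contrast would vanish.
* **Bookkeeping** — exact true/false counts per system are recorded and
  tested against the alignments.

All randomness derives from one seed through named per-component streams
(CRC32 of the stream name mixed into the seed), so each piece is
independently reproducible and derived seeds stay below 2³¹.

What the fixtures do **not** emulate: lexical content (labels are
synthetic tokens, so nothing lexical can be evaluated), repository-style
mapping retrieval, logical definitions/cross-products, and realistic
inter-system error correlation (systems err independently given the
confusability structure; real systems share lexical failure modes).
Passing tests therefore demonstrate the correctness of the evaluation
machinery, not claims about any particular real matcher.

## Numerical and procedural choices

* Published-table rounding is decimal half-up at 2 decimals, applied only
  at the reporting boundary.
* Alignment serialization orders cells lexicographically by (source,
  target, relation); report bundles are byte-identical across runs at a
  fixed seed, and the run manifest records SHA-256 hashes of every input.
* Vote thresholds default to {2, 3}; the review cap defaults to 30;
  consensus denominators use the number of contributing families.
* Problem sizes in the test and acceptance runs (30-node entailment
  instances × 200, 1000-mapping parameter recovery, 10⁴ oracle queries,
  100-fixture property sweeps) are chosen so each property is measured
  with comfortable statistical margin at interactive runtimes.
* The TSV dialect is tab-separated UTF-8 with `#` comments; identifiers
  are compared as exact trimmed strings.

## Known limitations

* Structural entailment is sound and complete only for told taxonomic
  axioms; expressive OWL content requires plugging a reasoner behind the
  `entails` interface.
* OWL files are not parsed directly; convert to OBO or edge-list first.
* Mapping repair is absent by design: incoherence is reported, not fixed.
* The oracle models a memoryless, symmetrically erring expert; request
  strategies of interactive matchers are the caller's to implement.
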