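# Methods

This note documents the models, parameters, numerical choices and
limitations behind `lbdkit`. Notation: A = initial (disease) term,
B = linking (physiological) term, C = target (substance) term; a
*sentence instance* is one ordered candidate pair of entity mentions in
one parsed sentence.

## Sentence representation

Instances carry tokens (surface, lemma, POS, punctuation flag), a
dependency parse, entity mentions with concept IDs (CUIs) and semantic
types, one candidate pair, and an optional ±1 relation label. A
sentence with more than two eligible mentions yields one instance per
ordered pair. Spans are token-indexed, 0-based, half-open; a
multi-token mention's head is its last token — a deterministic stand-in
for parser head information. The pair is canonicalized to token order;
discovery code identifies the anchor (query) mention by CUI, never by
pair position, so reversed surface orders ("B in A") are handled
uniformly.

### Relevance filters

Two filters precede classification and discovery. The semantic-type
filter keeps a sentence only if its linking-slot mention carries one of
nine functional types (Biologic/Cell/Molecular/Organism/Organ-or-tissue
/Pathologic/Physiologic function, Finding, Phenomenon or process) and —
for B–C instances — its target slot one of five substance types
(Organic chemical, Lipid, Pharmacologic substance, Vitamin, "Element,
ion, or isotope"). Unknown type strings count as not-allowed and are
tallied, never fatal. The general-concept filter removes overly broad
concepts, defined as the objects of ISA / PART_OF / LOCATION_OF
predication triples; it applies to **both** paired mentions by default.
Whether it should touch the anchor term as well as the linking term is
genuinely open; the choice is configurable (`apply_general_to`).

## The two views

**Word features.** Up to `window` (default 3) non-punctuation words
left of the first entity (`l_`), every non-punctuation word strictly
between the pair (`m_`), up to `window` words right of the second
entity (`r_`); one Boolean per relationship-word and per negation-word
lexicon hit among the sentence lemmas; one integer entity-distance
feature (non-punctuation words strictly between the mentions,
optionally scaled by `distance_scale`). Window and middle words are
lemmas, lowercased — surface forms would work equally well; lemmas were
chosen and made the single convention. Mention tokens contribute their
CUI (at the head token) instead of lexical material, and mention
interiors never leak into windows. Features are Boolean presence flags,
so duplicate middle words collapse. The shipped relationship lexicon is
a ~60-entry curated seed (verbs and nominalizations such as *induce*,
*inhibit*, *modulate*, plus common participle forms); production use
should supply a fuller domain list via `WordLists.from_files`.

**All-paths graph kernel.** Per instance one directed graph, the
disjoint union of:

* *parse structure subgraph* (PSS): a word vertex per token (labels
  lemma + POS), a link vertex per dependency edge (label: relation),
  edges governor→link→dependent. The shortest undirected path between
  the two entity heads is computed on this bipartite word/link graph
  with unit costs; ties are broken by the lexicographically smallest
  vertex-index sequence. Vertices on the path have each label
  specialized with `_IP` (replacing the plain label; `ip_additive=True`
  keeps both); path edges carry `w_shortest` = 0.9, all other PSS edges
  `w_other` = 0.3. A disconnected pair degrades to {the two heads} with
  a warning.
* *linear order subgraph* (LOS): a word vertex per token chained left
  to right at weight 0.3, labels tagged `_B` / `_M` / `_A` for
  positions before the first entity, from it through the second, and
  after. The entity tokens themselves are tagged `_M`; LOS edges never
  receive the 0.9 shortest-path weight (shortest paths are a parse
  notion). Both choices were open and are now fixed conventions.

Candidate entities are anonymized to `ENTITY1`/`ENTITY2` (other known
mentions: `ENTITY`), POS labels retained. Edges are directed by
default, which guarantees convergence on trees and chains;
`symmetrize_edges` adds reverse edges at equal weight.

The graph matrix is the exact closed form G = Lᵀ((I−A)⁻¹−I)L, computed
by dense inversion (sentence graphs have a few dozen vertices). A
spectral radius ≥ 1 is a hard error — silently rescaling weights would
change the model. Entries below 1e-12 are dropped as inversion dust;
true walk weights are orders of magnitude larger. G is stored sparsely
keyed by label pairs, and a collection of graphs is laid out as rows of
an append-only label-pair space, so the kernel k(G,G′) = ⟨G,G′⟩ (and
whole Gram/cross-kernel matrices) reduce to sparse matrix products,
independent of corpus order. Normalization divides by √(k₁₁k₂₂), with
0 when a self-kernel vanishes; Gram matrices are symmetrized by
averaging with their transpose to remove float asymmetry (≤1e-16).

The test suite checks the closed form against an independent truncated
walk enumeration (accumulated powers of A, 150 terms: with spectral
radius ≤ 0.8 the geometric tail is below 1e-13, far inside the 1e-9
assertion) on 120 random graphs, plus PSD, monotonicity and
vertex-relabeling invariance properties.

## Classifiers and metrics

Both views use SVMs (scikit-learn SVC): precomputed kernel for the
graph view, linear kernel for the sparse word vectors. C defaults to
1.0 — no hyperparameter search is performed anywhere, and class
weights are unadjusted by default. Confidence is the signed decision
margin; probabilities are deliberately not calibrated, since co-training
only needs a total order. Precision, recall and F are reported on the
0–100 scale with F = 0 when P + R = 0. Cohen's kappa is the closed form
on a 2×2 count table with marginal-product chance agreement; perfect
observed agreement returns 1 even at degenerate marginals (for a 2×2
table, chance agreement 1 in fact forces observed agreement 1).

## Co-training

Defaults: 5 rounds, selection fraction 0.10, pool sections
(2000, 3000, 4000, 5000, 6000) — the canonical schedule that grows a
500-sentence seed to 900/1,500/2,300/3,300/4,500. Pool sections are a
seeded permutation of the unlabeled corpus consumed left to right;
consumed instances never return and pseudo-labels are never revised.
Each round, each view's model scores its section; the top and bottom
⌊fraction·n⌋ (ties: stable input order) become positive/negative
pseudo-labeled examples for the *other* view. If both views pick the
same instance with opposite labels in one round it is discarded from
both — this is the one case where round sizes fall short of the closed
form |Tʳ| = |T⁰| + 2·Σ⌊fraction·nᵢ⌋. Models retrain from scratch every
round (no warm start) for determinism. `pick_model` selects the
best-held-out-F (view, round) pair, ties to the earlier round — the
model-selection rule is explicit rather than hard-coded because "best
F" and "last round" can disagree.

## Discovery

Closed discovery classifies pre-filtered A-side and C-side sentence
streams, takes the intersection of linking CUIs positive on both sides,
and reports S = n/N·100 with N = all distinct A-side linking
candidates after filtering (the natural reading of "terms related to
the initial term"; the alternative — counting before general-concept
filtering — would only shrink S). N = 0 yields S = 0 with a warning
rather than an error.

Open discovery is filter → AB-classify → filter → BC-classify → score.
The default scorer is the number of distinct effective B terms linking
to a C (ties: total supporting sentences, then CUI) — an explicit,
injectable stand-in, since published scoring rules for this step are
system-specific. Ranks are competition-style (equal scores share the
smaller rank). `combine_result_sets` intersects two rankings and sums
raw scores; score-scale compatibility is the caller's contract.

## Synthetic corpora

The generator emulates the regime the real pipeline faces: sentences
pairing a disease with a functional-type concept, 45% positives (the
class balance of the manually annotated agreement table), single-token
mentions whose semantic types are drawn from the real filter
vocabulary, and deterministic parses — relation templates attach both
entity heads to the verb (nsubj/dobj) over a right-branching chain, so
the PSS shortest path passes through the verb. Positive templates:
explicit relation verb, "B in A", "A can change B". Negative templates:
coordination ("A and B"), taxonomic copula ("A is a B"), and negated
relations. The label is a deterministic function of the template;
`noise_rate` flips labels, never text, so the planted rule stays
recoverable and co-training's effect is measurable. Discovery corpora
plant A→{B…}→C chains with configurable support, 50 single-link decoy
chains, dead-end B terms (AB-positive, BC-negative) and co-occurrence
noise by default.

What passing synthetic tests shows — and does not. With clean labels
the planted rule is exactly realizable in both views, so held-out F
near 100% demonstrates correct plumbing and parameter recovery, not
real-corpus performance: real sentences have paraphrase variety, parse
errors, multi-token and nested mentions, and annotation ambiguity that
the templates deliberately omit. Reported real-corpus F-scores (high
70s–80s) are not reproducible here because those corpora were never
released; the recovery experiments instead verify the *relative* claim
that co-training does not degrade the seed-only classifiers (checked
over ten seeds).

Experiment sizes (1,000-sentence corpora, 500/500 train/test,
100-sentence co-training seeds with three 130-instance pool sections)
were chosen to make a full ten-seed replication a minutes-scale,
single-core run while leaving the schedule non-trivial.

## Known limitations

* No NER, parsing, or concept normalization: mentions and parses must
  arrive pre-computed (JSON-lines or CoNLL-U + standoff).
* The graph kernel's dense inversion is fine for sentence graphs but
  not for document-scale graphs.
* The shipped relationship lexicon is a seed, not the full curated
  list a production deployment would use.
* Oracle classifiers in the CLI discovery commands: shell-level
  `closed`/`open` use gold labels (for validating pipelines on
  synthetic data); wiring trained models into discovery is a library
  operation (`closed_discovery(..., ab_classify=...)`).
* Scores from different systems are summed un-normalized when
  combining result sets, mirroring the simplest combination rule.
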