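"""Synthetic annotated corpora with known ground truth.

Real training corpora for the AB/BC relation models are built from
Medline sentences and are not redistributable, so every pipeline stage
here is exercised on generated corpora instead: templated sentences
containing two typed entity mentions, deterministic synthetic dependency
trees, a planted labeling rule mirroring the annotation criteria used
for the real corpora, and planted A–B–C chains with distractors for the
discovery engines.

The labeling rule is the annotation guideline turned into code: a
sentence asserting a relation (an explicit relationship verb between the
entities, or the special patterns "B in A" / "A can change B") is
positive; bare co-occurrence ("A and B"), taxonomic copulas ("A is a
B"), and negated relations (negation word + relationship verb) are
negative.  Label noise flips labels, never text, so the planted rule
stays recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np

from lbdkit.corpus import AnnotatedSentence, DependencyEdge, EntityMention, Token

__all__ = [
    "GeneratorConfig",
    "PlantedChain",
    "GroundTruth",
    "generate_corpus",
    "generate_discovery_corpora",
]

LINKING_TYPES = (
    "Biologic function", "Cell function", "Finding", "Molecular function",
    "Organism function", "Organ or tissue function", "Pathologic function",
    "Phenomenon or process", "Physiologic function",
)
TARGET_TYPES = (
    "Organic chemical", "Lipid", "Pharmacologic substance", "Vitamin",
    "Element, ion, or isotope",
)
DISEASE_TYPE = "Disease or Syndrome"

REL_VERBS = (
    "induce", "inhibit", "cause", "activate", "modulate", "reduce",
    "increase", "suppress", "stimulate", "regulate", "elevate", "attenuate",
)
FILLERS = (
    "patient", "study", "level", "outcome", "cohort", "sample",
    "baseline", "subject", "measurement", "profile", "serum", "tissue",
)
NEG_WORDS = ("not", "no", "never")

POSITIVE_KINDS = ("relation", "b_in_a", "change")
NEGATIVE_KINDS = ("coord", "copula", "negrel")


@dataclass(frozen=True)
class PlantedChain:
    """A ground-truth A→{B…}→C chain with per-edge sentence support."""

    a: str
    bs: tuple[str, ...]
    c: str
    support_ab: int = 2
    support_bc: int = 2


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for corpus generation.

    Defaults mirror the annotated-corpus regime the pipeline targets: a
    1,000-sentence labeled sample (split 500/500 into train and test by
    the experiments that consume it) with roughly 45% positives — the
    class balance of the manually annotated agreement table — and clean
    labels unless ``noise_rate`` is raised.
    """

    n_sentences: int = 1000
    n_entities: int = 40      # per role pool (diseases and linking terms)
    n_verbs: int = 10
    n_fillers: int = 10
    p_positive: float = 0.45
    p_negation: float = 0.3   # share of negatives that are negated relations
    p_special_pattern: float = 0.2  # share of positives using B-in-A / change
    noise_rate: float = 0.0
    seed: int = 0
    planted_chains: tuple[PlantedChain, ...] = ()
    distractor_chains: int = 50
    dead_end_terms: int = 5

    def __post_init__(self) -> None:
        for p in (self.p_positive, self.p_negation, self.p_special_pattern,
                  self.noise_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of range: {p}")
        if self.n_sentences < 1:
            raise ValueError("n_sentences must be positive")


@dataclass
class GroundTruth:
    """Gold labels (pre-noise) and planted-chain expectations."""

    labels: dict[str, str] = field(default_factory=dict)
    effective_b: dict[str, set[str]] = field(default_factory=dict)  # per A cui
    expected_top: dict[str, str] = field(default_factory=dict)      # A -> C


@dataclass(frozen=True)
class _Entity:
    cui: str
    name: str
    semtype: str


def _pools(cfg: GeneratorConfig):
    diseases = [
        _Entity(f"C1{i:03d}", f"disease{i}", DISEASE_TYPE)
        for i in range(cfg.n_entities)
    ]
    linking = [
        _Entity(f"C2{i:03d}", f"process{i}", LINKING_TYPES[i % len(LINKING_TYPES)])
        for i in range(cfg.n_entities)
    ]
    verbs = list(REL_VERBS[: max(1, cfg.n_verbs)])
    fillers = list(FILLERS[: max(1, cfg.n_fillers)])
    return diseases, linking, verbs, fillers


def _tok(i: int, surface: str, pos: str, lemma: str | None = None,
         punct: bool = False) -> Token:
    return Token(index=i, surface=surface, lemma=lemma or surface.lower(),
                 pos=pos, is_punct=punct)


def _build_sentence(
    sid: str,
    source: str,
    kind: str,
    ent1: _Entity,
    ent2: _Entity,
    verb: str,
    filler_a: str,
    filler_b: str,
    neg: str,
) -> tuple[AnnotatedSentence, str]:
    """Realize one template; returns the sentence and its rule label.

    ``ent1`` is the anchor-role entity (A for AB corpora, B for BC) and
    ``ent2`` the other; the ``b_in_a`` pattern reverses surface order.
    """
    words: list[tuple[str, str]]  # (surface, pos); entities marked inline
    if kind == "relation":
        words = [("the", "DT"), (filler_a, "NN"), ("of", "IN"), ("@1", ""),
                 (verb + "s", "VBZ"), ("@2", ""), ("in", "IN"),
                 (filler_b, "NN"), (".", "PUNCT")]
        verb_slot = 4
    elif kind == "change":
        words = [("@1", ""), ("can", "MD"), ("change", "VB"), ("@2", ""),
                 ("in", "IN"), (filler_a, "NN"), (".", "PUNCT")]
        verb_slot = 2
    elif kind == "b_in_a":
        words = [("elevated", "JJ"), ("@2", ""), ("in", "IN"), ("@1", ""),
                 ("with", "IN"), (filler_a, "NN"), (".", "PUNCT")]
        verb_slot = None
    elif kind == "coord":
        words = [("@1", ""), ("and", "CC"), ("@2", ""), ("were", "VBD"),
                 ("common", "JJ"), ("in", "IN"), (filler_a, "NN"),
                 (".", "PUNCT")]
        verb_slot = None
    elif kind == "copula":
        words = [("@1", ""), ("is", "VBZ"), ("a", "DT"), ("@2", ""),
                 ("of", "IN"), (filler_a, "NN"), (".", "PUNCT")]
        verb_slot = None
    elif kind == "negrel":
        words = [("@1", ""), ("does", "VBZ"), (neg, "RB"), (verb, "VB"),
                 ("@2", ""), ("in", "IN"), (filler_a, "NN"), (".", "PUNCT")]
        verb_slot = 3
    else:
        raise ValueError(f"unknown template kind {kind!r}")

    tokens: list[Token] = []
    spans: dict[str, int] = {}
    for i, (surface, pos) in enumerate(words):
        if surface == "@1":
            spans["m1"] = i
            tokens.append(_tok(i, ent1.cui, "NN", lemma=ent1.cui.lower()))
        elif surface == "@2":
            spans["m2"] = i
            tokens.append(_tok(i, ent2.cui, "NN", lemma=ent2.cui.lower()))
        elif surface == verb + "s" and verb_slot == i:
            tokens.append(_tok(i, surface, pos, lemma=verb))
        elif pos == "PUNCT":
            tokens.append(_tok(i, surface, pos, lemma=surface, punct=True))
        elif surface == "is":
            tokens.append(_tok(i, surface, pos, lemma="be"))
        elif surface == "were":
            tokens.append(_tok(i, surface, pos, lemma="be"))
        elif surface == "does":
            tokens.append(_tok(i, surface, pos, lemma="do"))
        else:
            tokens.append(_tok(i, surface, pos))

    ent_idx = {spans["m1"], spans["m2"]}
    edges: list[DependencyEdge] = []
    if verb_slot is not None:
        first, second = sorted(ent_idx)
        edges.append(DependencyEdge(verb_slot, first, "nsubj"))
        edges.append(DependencyEdge(verb_slot, second, "dobj"))
        prev = None
        for i in range(len(tokens)):
            if i in ent_idx:
                continue
            if prev is not None:
                edges.append(DependencyEdge(prev, i, "dep"))
            prev = i
    else:
        for i in range(len(tokens) - 1):
            edges.append(DependencyEdge(i, i + 1, "dep"))

    mentions = [
        EntityMention("m1", spans["m1"], spans["m1"] + 1, ent1.cui, ent1.name,
                      ent1.semtype),
        EntityMention("m2", spans["m2"], spans["m2"] + 1, ent2.cui, ent2.name,
                      ent2.semtype),
    ]
    rule_label = "positive" if kind in POSITIVE_KINDS else "negative"
    sent = AnnotatedSentence(
        sentence_id=sid,
        source_id=source,
        tokens=tokens,
        edges=edges,
        mentions=mentions,
        pair=("m1", "m2"),
        label=rule_label,
        extra={"template": kind},
    )
    sent.canonicalize()
    sent.validate()
    return sent, rule_label


def generate_corpus(
    cfg: GeneratorConfig,
) -> tuple[list[AnnotatedSentence], GroundTruth]:
    """Generate a labeled relation corpus under the planted rule.

    Each sentence pairs a disease with a linking-type entity.  The
    sentence's ``label`` carries the observed (possibly noise-flipped)
    annotation; :class:`GroundTruth` keeps the rule's gold label.
    """
    rng = np.random.default_rng(cfg.seed)
    diseases, linking, verbs, fillers = _pools(cfg)
    truth = GroundTruth()
    sents: list[AnnotatedSentence] = []

    for i in range(cfg.n_sentences):
        sid = f"s{i:06d}"
        positive = rng.random() < cfg.p_positive
        if positive:
            if rng.random() < cfg.p_special_pattern:
                kind = POSITIVE_KINDS[1 + rng.integers(2)]
            else:
                kind = "relation"
        else:
            if rng.random() < cfg.p_negation:
                kind = "negrel"
            else:
                kind = "coord" if rng.random() < 0.5 else "copula"
        ent1 = diseases[rng.integers(len(diseases))]
        ent2 = linking[rng.integers(len(linking))]
        verb = verbs[rng.integers(len(verbs))]
        fa = fillers[rng.integers(len(fillers))]
        fb = fillers[rng.integers(len(fillers))]
        neg = NEG_WORDS[rng.integers(len(NEG_WORDS))]
        sent, rule_label = _build_sentence(
            sid, f"pm{i:06d}", kind, ent1, ent2, verb, fa, fb, neg
        )
        truth.labels[sid] = rule_label
        # always draw so corpora with different noise rates share text
        if rng.random() < cfg.noise_rate:
            sent.label = "negative" if rule_label == "positive" else "positive"
        sents.append(sent)
    return sents, truth


def _chain_entity(cui: str, role: str, index: int) -> _Entity:
    if role == "A":
        return _Entity(cui, cui.lower(), DISEASE_TYPE)
    if role == "B":
        return _Entity(cui, cui.lower(), LINKING_TYPES[index % len(LINKING_TYPES)])
    return _Entity(cui, cui.lower(), TARGET_TYPES[index % len(TARGET_TYPES)])


def generate_discovery_corpora(
    cfg: GeneratorConfig,
) -> tuple[list[AnnotatedSentence], dict[str, list[AnnotatedSentence]], GroundTruth]:
    """Build A-side and B-keyed corpora with planted A–B–C chains.

    For every planted chain, each B gets ``support_ab`` positive A–B
    sentences and ``support_bc`` positive B–C sentences.  Distractors
    comprise full single-support chains to decoy targets (so the planted
    C must out-score ``distractor_chains`` competitors), dead-end linking
    terms whose B-side sentences are negative, and negative co-occurrence
    sentences on the A side.
    """
    if not cfg.planted_chains:
        raise ValueError("generate_discovery_corpora requires planted_chains")
    rng = np.random.default_rng(cfg.seed)
    _, _, verbs, fillers = _pools(cfg)
    truth = GroundTruth()
    a_sents: list[AnnotatedSentence] = []
    b_corpus: dict[str, list[AnnotatedSentence]] = {}
    counter = 0

    def _emit(kind: str, ent1: _Entity, ent2: _Entity) -> AnnotatedSentence:
        nonlocal counter
        sid = f"d{counter:06d}"
        counter += 1
        sent, rule_label = _build_sentence(
            sid, f"pmd{counter:06d}", kind, ent1, ent2,
            verbs[rng.integers(len(verbs))],
            fillers[rng.integers(len(fillers))],
            fillers[rng.integers(len(fillers))],
            NEG_WORDS[rng.integers(len(NEG_WORDS))],
        )
        truth.labels[sid] = rule_label
        return sent

    b_index = 0
    for chain in cfg.planted_chains:
        a_ent = _chain_entity(chain.a, "A", 0)
        c_ent = _chain_entity(chain.c, "C", 0)
        effective: set[str] = set()
        for b in chain.bs:
            b_ent = _chain_entity(b, "B", b_index)
            b_index += 1
            for _ in range(chain.support_ab):
                a_sents.append(_emit("relation", a_ent, b_ent))
            for _ in range(chain.support_bc):
                b_corpus.setdefault(b, []).append(_emit("relation", b_ent, c_ent))
            if chain.support_ab > 0 and chain.support_bc > 0:
                effective.add(b)
        truth.effective_b[chain.a] = effective
        truth.expected_top[chain.a] = chain.c

        # full distractor chains: one B link each to a decoy target
        for j in range(cfg.distractor_chains):
            db = _chain_entity(f"{chain.a}_DB{j:03d}", "B", b_index)
            dc = _chain_entity(f"{chain.a}_DC{j:03d}", "C", j)
            b_index += 1
            a_sents.append(_emit("relation", a_ent, db))
            b_corpus.setdefault(db.cui, []).append(_emit("relation", db, dc))

        # dead-end linking terms: AB-positive, BC-side negative only
        for j in range(cfg.dead_end_terms):
            db = _chain_entity(f"{chain.a}_DE{j:03d}", "B", b_index)
            dc = _chain_entity(f"{chain.a}_XC{j:03d}", "C", j)
            b_index += 1
            a_sents.append(_emit("relation", a_ent, db))
            b_corpus.setdefault(db.cui, []).append(_emit("coord", db, dc))

        # A-side negative co-occurrences (never linking evidence)
        for j in range(cfg.dead_end_terms):
            db = _chain_entity(f"{chain.a}_NB{j:03d}", "B", b_index)
            b_index += 1
            a_sents.append(_emit("coord", a_ent, db))

    return a_sents, b_corpus, truth
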