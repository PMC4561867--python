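"""The lexical word-feature view of a candidate sentence pair.

Each sentence is reduced to a sparse Boolean vector: position-prefixed
neighboring words (``l_`` for up to three words left of the first
entity, ``m_`` for every word between the entities, ``r_`` for up to
three words right of the second entity), one relationship-word and one
negation-word indicator per list hit, and a single integer feature for
the word distance between the two entities.  The linear kernel on these
vectors is the "word features" view used by co-training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from lbdkit.corpus import AnnotatedSentence, CorpusError

try:
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    _pkg_files = None

__all__ = [
    "WordLists",
    "FeatureVector",
    "Vocabulary",
    "extract_features",
    "fit_vocabulary",
    "vectorize",
    "vectorize_many",
]

DISTANCE_FEATURE = "distance"
REL_PREFIX = "rel_"
NEG_PREFIX = "neg_"


def _read_wordlist(path: str | Path) -> frozenset[str]:
    terms = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.add(line.lower())
    return frozenset(terms)


@dataclass(frozen=True)
class WordLists:
    """Relationship-word and negation-word lexicons (lowercased lemmas)."""

    relationship_words: frozenset[str]
    negative_words: frozenset[str]

    @classmethod
    def default(cls) -> "WordLists":
        data = _pkg_files("lbdkit") / "data"
        rel = frozenset(
            t.lower()
            for t in (data / "relationship_words.txt").read_text().splitlines()
            if t.strip() and not t.startswith("#")
        )
        neg = frozenset(
            t.lower()
            for t in (data / "negative_words.txt").read_text().splitlines()
            if t.strip() and not t.startswith("#")
        )
        return cls(rel, neg)

    @classmethod
    def from_files(
        cls, relationship_path: str | Path, negative_path: str | Path
    ) -> "WordLists":
        return cls(_read_wordlist(relationship_path), _read_wordlist(negative_path))


@dataclass
class FeatureVector:
    """Sparse named features; Booleans are 1, distance is a count."""

    features: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.features[name]

    def __contains__(self, name: str) -> bool:
        return name in self.features

    def names(self) -> set[str]:
        return set(self.features)


def _effective_items(sent: AnnotatedSentence) -> list[tuple[int, str]]:
    """Token stream with mentions collapsed to their CUI at the head token.

    Returns (token_index, item_string) for non-punct positions; interior
    tokens of multi-token mentions are dropped so a mention contributes
    exactly one item, its CUI.
    """
    by_token: dict[int, tuple[str, bool]] = {}
    for m in sent.mentions:
        for i in range(m.start, m.end):
            by_token[i] = (m.cui, i == m.head)
    items = []
    for t in sent.tokens:
        if t.index in by_token:
            cui, is_head = by_token[t.index]
            if is_head:
                items.append((t.index, cui))
        elif not t.is_punct:
            items.append((t.index, t.lemma.lower()))
    return items


def extract_features(
    sent: AnnotatedSentence, lists: WordLists, window: int = 3
) -> FeatureVector:
    """Extract the word-feature view for the sentence's candidate pair.

    Emits ``l_``/``m_``/``r_``-prefixed neighboring-word features (window
    words outside the pair, all words strictly between it), one
    ``rel_<word>`` flag per relationship word among the sentence lemmas,
    one ``neg_<word>`` flag per negation word, and the entity distance
    (number of non-punctuation words strictly between the mentions).
    """
    if not sent.pair or len(sent.pair) != 2:
        raise CorpusError(f"sentence {sent.sentence_id!r}: candidate pair missing")
    e1, e2 = sent.e1, sent.e2
    feats: dict[str, float] = {}

    items = _effective_items(sent)
    left = [w for i, w in items if i < e1.start]
    middle = [w for i, w in items if e1.end <= i and i < e2.start and i >= e1.end]
    right = [w for i, w in items if i >= e2.end]

    for w in left[-window:]:
        feats[f"l_{w}"] = 1.0
    for w in middle:
        feats[f"m_{w}"] = 1.0
    for w in right[:window]:
        feats[f"r_{w}"] = 1.0

    lemmas = {t.lemma.lower() for t in sent.tokens if not t.is_punct}
    for w in lemmas & lists.relationship_words:
        feats[f"{REL_PREFIX}{w}"] = 1.0
    for w in lemmas & lists.negative_words:
        feats[f"{NEG_PREFIX}{w}"] = 1.0

    feats[DISTANCE_FEATURE] = float(
        sum(1 for t in sent.tokens
            if e1.end <= t.index < e2.start and not t.is_punct)
    )
    return FeatureVector(feats)


@dataclass
class Vocabulary:
    """Feature-name → dense column index map; frozen after fitting."""

    index: dict[str, int] = field(default_factory=dict)
    frozen: bool = False

    def __len__(self) -> int:
        return len(self.index)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.index, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "Vocabulary":
        return cls(index=json.loads(Path(path).read_text()), frozen=True)


def fit_vocabulary(vectors: Iterable[FeatureVector]) -> Vocabulary:
    """Assign dense column indices to every distinct feature name.

    Names are ordered lexicographically, so the mapping is independent of
    input order. At least one vector is required.
    """
    names: set[str] = set()
    count = 0
    for vec in vectors:
        names.update(vec.features)
        count += 1
    if count == 0:
        raise ValueError("fit_vocabulary requires at least one feature vector")
    return Vocabulary(
        index={name: i for i, name in enumerate(sorted(names))}, frozen=True
    )


def vectorize(
    vector: FeatureVector, vocab: Vocabulary, distance_scale: float = 1.0
) -> sparse.csr_matrix:
    """Map a named feature vector to a 1×|V| sparse row.

    Out-of-vocabulary names are dropped silently; the distance feature is
    divided by ``distance_scale`` (default 1, i.e. raw word count).
    """
    if not vocab.frozen:
        raise ValueError("vocabulary must be frozen before vectorizing")
    cols, vals = [], []
    for name, val in vector.features.items():
        j = vocab.index.get(name)
        if j is None:
            continue
        if name == DISTANCE_FEATURE:
            val = val / distance_scale
        if val == 0:
            continue
        cols.append(j)
        vals.append(val)
    return sparse.csr_matrix(
        (vals, (np.zeros(len(cols), dtype=int), cols)),
        shape=(1, len(vocab)),
    )


def vectorize_many(
    vectors: Sequence[FeatureVector], vocab: Vocabulary,
    distance_scale: float = 1.0,
) -> sparse.csr_matrix:
    if not vectors:
        return sparse.csr_matrix((0, len(vocab)))
    return sparse.vstack(
        [vectorize(v, vocab, distance_scale) for v in vectors], format="csr"
    )
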