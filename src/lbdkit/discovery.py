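"""Closed- and open-discovery engines over the AB and BC models.

Closed discovery tests a hypothesis: given a disease A and a substance
C, the AB model classifies A-side sentences and the BC model C-side
sentences; the linking concepts appearing in positives on *both* sides
are the effective linking terms, summarized by the ratio
S = n/N·100% where N counts every linking-term candidate related to the
initial term.  Open discovery generates hypotheses: AB-positive
sentences yield linking terms B, the semantic-type and general-concept
filters prune them, BC classification of each surviving B's sentences
yields target candidates C, and a scorer ranks the C terms.  Two
rankings (e.g. from different extraction systems) can be combined by
intersecting their term sets and summing scores.

Classifiers are passed as callables mapping a list of sentences to ±1
predictions, so trained kernel models and oracle (gold-label) classifiers
plug in identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from lbdkit.corpus import (
    AnnotatedSentence,
    GeneralConceptList,
    SemanticTypeFilter,
    filter_sentences,
)

__all__ = [
    "LinkingTermSet",
    "RankedTermList",
    "ClosedDiscoveryResult",
    "OpenDiscoveryResult",
    "closed_discovery",
    "open_discovery",
    "default_scorer",
    "combine_result_sets",
    "effective_ratio",
    "oracle_classifier",
]

Classifier = Callable[[Sequence[AnnotatedSentence]], Sequence[int]]


def oracle_classifier(sents: Sequence[AnnotatedSentence]) -> list[int]:
    """Classify by gold label — the ceiling for discovery experiments."""
    return [1 if s.label == "positive" else -1 for s in sents]


def effective_ratio(n: int, N: int) -> float:
    """S = n/N·100: the share of linking candidates that are effective."""
    if not (0 <= n <= N):
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if N == 0:
        raise ValueError("effective ratio undefined for N = 0")
    return 100.0 * n / N


@dataclass
class LinkingTermSet:
    """Effective linking CUIs with their supporting sentence ids per side."""

    terms: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def add(self, cui: str, side: str, sentence_id: str) -> None:
        self.terms.setdefault(cui, {"AB": [], "BC": []})[side].append(sentence_id)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, cui: str) -> bool:
        return cui in self.terms


@dataclass
class RankedTermList:
    """(cui, score, rank) triples, scores non-increasing, ranks 1-based.

    Equal scores share the smaller rank (competition ranking); ordering
    among equals is deterministic via the provided sort key.
    """

    items: list[tuple[str, float, int]] = field(default_factory=list)

    @classmethod
    def from_scores(
        cls,
        scores: Mapping[str, float],
        tiebreak: Callable[[str], tuple] | None = None,
    ) -> "RankedTermList":
        key = tiebreak or (lambda cui: (cui,))
        ordered = sorted(scores, key=lambda c: (-scores[c],) + key(c))
        items: list[tuple[str, float, int]] = []
        rank = 0
        prev: float | None = None
        for pos, cui in enumerate(ordered, start=1):
            s = scores[cui]
            if prev is None or s < prev:
                rank = pos
                prev = s
            items.append((cui, s, rank))
        return cls(items)

    def scores(self) -> dict[str, float]:
        return {cui: s for cui, s, _ in self.items}

    def rank_of(self, cui: str) -> int | None:
        for c, _, r in self.items:
            if c == cui:
                return r
        return None

    def __len__(self) -> int:
        return len(self.items)


@dataclass
class ClosedDiscoveryResult:
    effective_terms: LinkingTermSet
    n: int
    N: int
    ratio: float

    def to_dict(self) -> dict:
        return {
            "n": self.n, "N": self.N, "ratio": round(self.ratio, 2),
            "effective_terms": self.effective_terms.terms,
        }


@dataclass
class OpenDiscoveryResult:
    ranking: RankedTermList
    provenance: dict[str, dict[str, int]]  # C cui -> {B cui: support count}
    effective_b: set[str] = field(default_factory=set)

    def to_dict(self) -> dict:
        return {
            "ranking": [
                {"cui": c, "score": s, "rank": r} for c, s, r in self.ranking.items
            ],
            "provenance": self.provenance,
            "effective_b": sorted(self.effective_b),
        }


def _linking_mention(sent: AnnotatedSentence, anchor_cuis: frozenset[str]):
    e1, e2 = sent.e1, sent.e2
    return e2 if e1.cui in anchor_cuis else e1


def closed_discovery(
    a_sents: Iterable[AnnotatedSentence],
    c_sents: Iterable[AnnotatedSentence],
    ab_classify: Classifier,
    bc_classify: Classifier,
    initial_cuis: Iterable[str],
    target_cuis: Iterable[str],
) -> ClosedDiscoveryResult:
    """Find effective linking terms between a disease and a substance.

    ``a_sents`` pair the initial term with a linking candidate and
    ``c_sents`` pair a linking candidate with the target term; both are
    expected pre-filtered (semantic types, general concepts).  The
    effective set is the intersection of the linking CUIs of AB-positive
    and BC-positive sentences; N counts all distinct A-side linking
    candidates.
    """
    initial = frozenset(initial_cuis)
    target = frozenset(target_cuis)
    a_list = list(a_sents)
    c_list = list(c_sents)

    all_a_side: set[str] = set()
    ab_support: dict[str, list[str]] = {}
    if a_list:
        preds = ab_classify(a_list)
        for sent, p in zip(a_list, preds):
            b = _linking_mention(sent, initial)
            all_a_side.add(b.cui)
            if p > 0:
                ab_support.setdefault(b.cui, []).append(sent.sentence_id)

    bc_support: dict[str, list[str]] = {}
    if c_list:
        preds = bc_classify(c_list)
        for sent, p in zip(c_list, preds):
            if p > 0:
                b = _linking_mention(sent, target)
                bc_support.setdefault(b.cui, []).append(sent.sentence_id)

    effective = LinkingTermSet()
    for cui in sorted(set(ab_support) & set(bc_support)):
        for sid in ab_support[cui]:
            effective.add(cui, "AB", sid)
        for sid in bc_support[cui]:
            effective.add(cui, "BC", sid)

    N = len(all_a_side)
    if N == 0:
        warnings.warn("closed discovery: no A-side linking candidates; S=0")
        ratio = 0.0
    else:
        ratio = effective_ratio(len(effective), N)
    return ClosedDiscoveryResult(
        effective_terms=effective, n=len(effective), N=N, ratio=ratio
    )


def default_scorer(
    provenance: Mapping[str, Mapping[str, int]],
) -> dict[str, float]:
    """Score each target term by its number of distinct linking terms.

    A stand-in for system-specific scoring rules: more independent B
    chains into a C term means stronger converging evidence.  Ties are
    broken downstream by total supporting-sentence count, then CUI.
    """
    return {cui: float(len(bs)) for cui, bs in provenance.items()}


def open_discovery(
    a_sents: Iterable[AnnotatedSentence],
    corpus_b: Callable[[str], Sequence[AnnotatedSentence]],
    ab_classify: Classifier,
    bc_classify: Classifier,
    filter: SemanticTypeFilter,
    general: GeneralConceptList,
    initial_cuis: Iterable[str],
    scorer: Callable[[Mapping[str, Mapping[str, int]]], Mapping[str, float]]
    | None = None,
) -> OpenDiscoveryResult:
    """Generate ranked target-term hypotheses starting from a disease.

    Stage 1: AB-positive A-side sentences yield linking candidates B.
    Stage 2: semantic-type and general-concept filters prune them.
    Stage 3: each surviving B's sentences (from ``corpus_b``) are
    BC-classified; positives contribute target CUIs with allowed target
    semantic types.  Stage 4: ``scorer`` (default: distinct-B count)
    scores every C and the list is ranked.
    """
    initial = frozenset(initial_cuis)
    scorer = scorer or default_scorer

    # stage 1+2: filtered A-side sentences -> AB-positive linking terms
    filtered_a = list(
        filter_sentences(a_sents, filter, general, role="AB",
                         anchor_cuis=initial)
    )
    b_terms: set[str] = set()
    if filtered_a:
        preds = ab_classify(filtered_a)
        for sent, p in zip(filtered_a, preds):
            if p > 0:
                b_terms.add(_linking_mention(sent, initial).cui)

    # stage 3: BC classification per linking term
    provenance: dict[str, dict[str, int]] = {}
    support_totals: dict[str, int] = {}
    for b in sorted(b_terms):
        sents = list(corpus_b(b))
        if not sents:
            continue
        preds = bc_classify(sents)
        for sent, p in zip(sents, preds):
            if p <= 0:
                continue
            c_m = _linking_mention(sent, frozenset({b}))
            if c_m.semtype not in filter.target_types or c_m.cui in general:
                continue
            provenance.setdefault(c_m.cui, {})
            provenance[c_m.cui][b] = provenance[c_m.cui].get(b, 0) + 1

    # stage 4: score and rank
    raw_scores = scorer(provenance) if provenance else {}
    scores: dict[str, float] = {}
    for cui in provenance:
        try:
            scores[cui] = float(raw_scores[cui])
        except Exception as exc:
            raise RuntimeError(f"scorer failed on term {cui!r}: {exc}") from exc
    for cui, bs in provenance.items():
        support_totals[cui] = sum(bs.values())
    ranking = RankedTermList.from_scores(
        scores, tiebreak=lambda c: (-support_totals.get(c, 0), c)
    )
    return OpenDiscoveryResult(
        ranking=ranking, provenance=provenance, effective_b=b_terms
    )


def combine_result_sets(r1: RankedTermList, r2: RankedTermList) -> RankedTermList:
    """Intersect two rankings, summing scores for shared terms.

    Score scales must be comparable — the caller's contract; no
    normalization is applied.
    """
    s1, s2 = r1.scores(), r2.scores()
    combined = {cui: s1[cui] + s2[cui] for cui in set(s1) & set(s2)}
    return RankedTermList.from_scores(combined)
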