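"""Data model and I/O for annotated relation-extraction corpora.

A corpus is a stream of sentences, each carrying tokens (with lemma and
part of speech), a dependency parse, typed entity mentions identified by
concept IDs (CUIs), and one ordered candidate pair of mentions that the
relation classifiers judge.  Two relevance filters operate on such
streams: a semantic-type filter restricting the candidate linking and
target concepts to functionally meaningful categories, and a
general-concept filter removing overly broad concepts (e.g. "disease")
collected from ISA / PART_OF / LOCATION_OF predication triples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import yaml

try:  # importlib.resources for the packaged default filter
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    _pkg_files = None

__all__ = [
    "Token",
    "EntityMention",
    "DependencyEdge",
    "AnnotatedSentence",
    "SemanticTypeFilter",
    "PredicationTriple",
    "GeneralConceptList",
    "CorpusError",
    "read_corpus",
    "write_corpus",
    "read_triples",
    "build_general_concept_list",
    "filter_sentences",
]

LABELS = ("positive", "negative", "unlabeled")

GENERAL_RELATIONS = frozenset({"ISA", "PART_OF", "LOCATION_OF"})


class CorpusError(ValueError):
    """Raised for records violating the corpus schema."""


@dataclass(frozen=True)
class Token:
    index: int
    surface: str
    lemma: str
    pos: str
    is_punct: bool = False


@dataclass(frozen=True)
class EntityMention:
    """An entity occurrence: token span [start, end), concept ID, type."""

    mention_id: str
    start: int
    end: int
    cui: str
    name: str
    semtype: str

    @property
    def head(self) -> int:
        """Head token index: the last token of the mention."""
        return self.end - 1


@dataclass(frozen=True)
class DependencyEdge:
    governor: int
    dependent: int
    relation: str


@dataclass
class AnnotatedSentence:
    """One candidate-pair instance over a parsed, entity-annotated sentence.

    ``pair`` holds the mention_ids of the two candidate entities; after
    :meth:`canonicalize` the first precedes the second in token order.
    Unknown input fields are kept opaquely in ``extra`` for round-trip.
    """

    sentence_id: str
    source_id: str
    tokens: list[Token]
    edges: list[DependencyEdge]
    mentions: list[EntityMention]
    pair: tuple[str, str]
    label: str = "unlabeled"
    extra: dict = field(default_factory=dict)

    def mention(self, mention_id: str) -> EntityMention:
        for m in self.mentions:
            if m.mention_id == mention_id:
                return m
        raise CorpusError(
            f"sentence {self.sentence_id!r}: pair references unknown "
            f"mention {mention_id!r}"
        )

    @property
    def e1(self) -> EntityMention:
        return self.mention(self.pair[0])

    @property
    def e2(self) -> EntityMention:
        return self.mention(self.pair[1])

    def canonicalize(self) -> "AnnotatedSentence":
        """Order the pair so e1 precedes e2 in token order."""
        a, b = self.mention(self.pair[0]), self.mention(self.pair[1])
        if (a.start, a.end) > (b.start, b.end):
            self.pair = (b.mention_id, a.mention_id)
        return self

    def validate(self) -> None:
        n = len(self.tokens)
        for i, t in enumerate(self.tokens):
            if t.index != i:
                raise CorpusError(
                    f"sentence {self.sentence_id!r}: token indices not "
                    f"consecutive from 0 (position {i} has index {t.index})"
                )
            if not t.is_punct and (not t.lemma or not t.pos):
                raise CorpusError(
                    f"sentence {self.sentence_id!r}: non-punct token {i} "
                    "has empty lemma or pos"
                )
        for e in self.edges:
            if e.governor == e.dependent:
                raise CorpusError(
                    f"sentence {self.sentence_id!r}: self-loop edge at "
                    f"{e.governor}"
                )
            if not (0 <= e.governor < n and 0 <= e.dependent < n):
                raise CorpusError(
                    f"sentence {self.sentence_id!r}: edge index out of range"
                )
        for m in self.mentions:
            if not (0 <= m.start < m.end <= n):
                raise CorpusError(
                    f"sentence {self.sentence_id!r}: mention {m.mention_id!r} "
                    f"span [{m.start},{m.end}) out of range"
                )
        if self.label not in LABELS:
            raise CorpusError(
                f"sentence {self.sentence_id!r}: bad label {self.label!r}"
            )
        e1, e2 = self.e1, self.e2
        if not (e1.end <= e2.start or e2.end <= e1.start):
            raise CorpusError(
                f"sentence {self.sentence_id!r}: candidate pair spans overlap"
            )


@dataclass(frozen=True)
class PredicationTriple:
    subject_cui: str
    relation: str
    object_cui: str


@dataclass
class GeneralConceptList:
    """Overly broad concepts to exclude; exact string match on CUIs."""

    concepts: frozenset[str] = frozenset()

    def __contains__(self, cui: str) -> bool:
        return cui in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneralConceptList":
        terms = set()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if line and not line.startswith("#"):
                terms.add(line)
        return cls(frozenset(terms))


@dataclass
class SemanticTypeFilter:
    """Allowed semantic types for linking (B) and target (C) concepts."""

    linking_types: frozenset[str]
    target_types: frozenset[str]

    @classmethod
    def default(cls) -> "SemanticTypeFilter":
        """The packaged default filter: 9 linking and 5 target types."""
        text = (_pkg_files("lbdkit") / "data" / "semantic_types.yaml").read_text()
        return cls.from_yaml_text(text)

    @classmethod
    def from_yaml_text(cls, text: str) -> "SemanticTypeFilter":
        doc = yaml.safe_load(text)
        return cls(
            linking_types=frozenset(doc["linking_types"]),
            target_types=frozenset(doc["target_types"]),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "SemanticTypeFilter":
        return cls.from_yaml_text(Path(path).read_text())


# ---------------------------------------------------------------------------
# JSON-lines corpus I/O

_MANDATORY = ("sentence_id", "source_id", "tokens", "mentions", "pair")


def _sentence_from_record(rec: dict, where: str) -> AnnotatedSentence:
    for key in _MANDATORY:
        if key not in rec:
            raise CorpusError(f"{where}: missing mandatory field {key!r}")
    tokens = [
        Token(
            index=i,
            surface=t["surface"],
            lemma=t.get("lemma", ""),
            pos=t.get("pos", ""),
            is_punct=bool(t.get("is_punct", False)),
        )
        for i, t in enumerate(rec["tokens"])
    ]
    edges = [
        DependencyEdge(int(e["governor"]), int(e["dependent"]), e["relation"])
        for e in rec.get("edges", [])
    ]
    mentions = [
        EntityMention(
            mention_id=m["mention_id"],
            start=int(m["start"]),
            end=int(m["end"]),
            cui=m["cui"],
            name=m.get("name", m["cui"]),
            semtype=m.get("semtype", ""),
        )
        for m in rec["mentions"]
    ]
    pair = tuple(rec["pair"])
    if len(pair) != 2:
        raise CorpusError(f"{where}: pair must have exactly two mention ids")
    known = {
        "sentence_id", "source_id", "tokens", "edges", "mentions",
        "pair", "label",
    }
    extra = {k: v for k, v in rec.items() if k not in known}
    sent = AnnotatedSentence(
        sentence_id=rec["sentence_id"],
        source_id=rec["source_id"],
        tokens=tokens,
        edges=edges,
        mentions=mentions,
        pair=pair,  # type: ignore[arg-type]
        label=rec.get("label", "unlabeled"),
        extra=extra,
    )
    sent.canonicalize()
    sent.validate()
    return sent


def sentence_to_record(sent: AnnotatedSentence) -> dict:
    rec = {
        "sentence_id": sent.sentence_id,
        "source_id": sent.source_id,
        "tokens": [
            {
                "surface": t.surface,
                "lemma": t.lemma,
                "pos": t.pos,
                "is_punct": t.is_punct,
            }
            for t in sent.tokens
        ],
        "edges": [
            {"governor": e.governor, "dependent": e.dependent,
             "relation": e.relation}
            for e in sent.edges
        ],
        "mentions": [
            {
                "mention_id": m.mention_id,
                "start": m.start,
                "end": m.end,
                "cui": m.cui,
                "name": m.name,
                "semtype": m.semtype,
            }
            for m in sent.mentions
        ],
        "pair": list(sent.pair),
        "label": sent.label,
    }
    rec.update(sent.extra)
    return rec


def read_corpus(
    path: str | Path, format: str = "jsonl", standoff: str | Path | None = None
) -> Iterator[AnnotatedSentence]:
    """Stream sentences from a corpus file.

    ``format`` is ``jsonl`` (one sentence object per line) or ``conllu``
    (CoNLL-U parses with a JSON-lines standoff sidecar carrying mentions,
    pair and label per sentence).  Records whose candidate spans overlap
    are skipped with a warning; structural violations are hard errors
    naming the offending field and line.
    """
    if format == "jsonl":
        yield from _read_jsonl(path)
    elif format == "conllu":
        if standoff is None:
            raise CorpusError("conllu format requires a standoff sidecar path")
        yield from _read_conllu(path, standoff)
    else:
        raise CorpusError(f"unknown corpus format {format!r}")


def _read_jsonl(path: str | Path) -> Iterator[AnnotatedSentence]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            where = f"{path}:{lineno}"
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{where}: invalid JSON ({exc})") from exc
            try:
                yield _sentence_from_record(rec, where)
            except CorpusError as exc:
                if "spans overlap" in str(exc):
                    warnings.warn(f"skipping record: {exc}")
                    continue
                raise


def write_corpus(sents: Iterable[AnnotatedSentence], path: str | Path) -> int:
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for sent in sents:
            fh.write(json.dumps(sentence_to_record(sent), sort_keys=True))
            fh.write("\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# CoNLL-U + standoff

def _read_conllu(path: str | Path, standoff: str | Path) -> Iterator[AnnotatedSentence]:
    # Minimal CoNLL-U consumption: ID/FORM/LEMMA/UPOS/HEAD/DEPREL columns;
    # multiword-token and empty-node lines are ignored.
    annos: dict[str, dict] = {}
    with open(standoff, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line:
                rec = json.loads(line)
                annos[rec["sentence_id"]] = rec

    sent_id = None
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("# sent_id"):
                sent_id = line.split("=", 1)[1].strip()
            elif line.startswith("#"):
                continue
            elif not line.strip():
                if rows:
                    yield _conllu_sentence(sent_id, rows, annos, f"{path}:{lineno}")
                sent_id, rows = None, []
            else:
                cols = line.split("\t")
                if len(cols) < 8:
                    raise CorpusError(
                        f"{path}:{lineno}: CoNLL-U row has {len(cols)} columns"
                    )
                if "-" in cols[0] or "." in cols[0]:
                    continue
                rows.append(cols)
    if rows:
        yield _conllu_sentence(sent_id, rows, annos, f"{path}:EOF")


_PUNCT_POS = {"PUNCT", ".", ",", ":", "``", "''", "-LRB-", "-RRB-"}


def _conllu_sentence(
    sent_id: str | None, rows: list[list[str]], annos: dict, where: str
) -> AnnotatedSentence:
    if sent_id is None:
        raise CorpusError(f"{where}: CoNLL-U block missing '# sent_id'")
    if sent_id not in annos:
        raise CorpusError(f"{where}: no standoff record for sentence {sent_id!r}")
    rec = annos[sent_id]
    tokens = [
        Token(
            index=i,
            surface=c[1],
            lemma=c[2] if c[2] != "_" else c[1].lower(),
            pos=c[3],
            is_punct=c[3] in _PUNCT_POS,
        )
        for i, c in enumerate(rows)
    ]
    edges = [
        DependencyEdge(int(c[6]) - 1, i, c[7])
        for i, c in enumerate(rows)
        if c[6] not in ("_", "0")
    ]
    full = dict(rec)
    full.setdefault("source_id", sent_id)
    full["sentence_id"] = sent_id
    full["tokens"] = [
        {"surface": t.surface, "lemma": t.lemma, "pos": t.pos,
         "is_punct": t.is_punct}
        for t in tokens
    ]
    full["edges"] = [
        {"governor": e.governor, "dependent": e.dependent, "relation": e.relation}
        for e in edges
    ]
    return _sentence_from_record(full, where)


# ---------------------------------------------------------------------------
# Predication triples and the general-concept list

def read_triples(path: str | Path) -> Iterator[PredicationTriple]:
    """Read subject/relation/object triples from a 3-column TSV."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise CorpusError(
                    f"{path}:{lineno}: expected 3 tab-separated columns"
                )
            yield PredicationTriple(cols[0], cols[1], cols[2])


def build_general_concept_list(
    triples: Iterable[PredicationTriple],
) -> GeneralConceptList:
    """Collect object CUIs of ISA / PART_OF / LOCATION_OF predications.

    The objects of these hierarchical relations are the overly broad
    concepts ("disease", "cell", ...) that drown out informative linking
    terms; any other relation is ignored.
    """
    objs = {t.object_cui for t in triples if t.relation in GENERAL_RELATIONS}
    return GeneralConceptList(frozenset(objs))


# ---------------------------------------------------------------------------
# Sentence filtering

def filter_sentences(
    sents: Iterable[AnnotatedSentence],
    filter: SemanticTypeFilter,
    general: GeneralConceptList,
    role: str,
    anchor_cuis: frozenset[str] | set[str] | None = None,
    apply_general_to: str = "both",
    stats: dict | None = None,
) -> Iterator[AnnotatedSentence]:
    """Keep sentences whose candidate concepts pass the relevance filters.

    ``role`` is ``"AB"`` (pair = disease anchor + linking candidate) or
    ``"BC"`` (pair = linking candidate + target candidate).  The linking
    slot must carry one of ``filter.linking_types``; for BC the target
    slot must additionally carry one of ``filter.target_types``.  When
    ``anchor_cuis`` is given, the anchor mention is identified by CUI
    rather than pair position.  General-concept filtering applies to both
    paired mentions by default (``apply_general_to`` in
    {"both", "linking"}).  Unknown semantic types are treated as
    not-allowed and tallied in ``stats`` if a dict is supplied.
    """
    if role not in ("AB", "BC"):
        raise ValueError(f"role must be 'AB' or 'BC', got {role!r}")
    known_types = filter.linking_types | filter.target_types
    if stats is not None:
        stats.setdefault("kept", 0)
        stats.setdefault("dropped_semtype", 0)
        stats.setdefault("dropped_general", 0)
        stats.setdefault("unknown_semtypes", set())

    for sent in sents:
        e1, e2 = sent.e1, sent.e2
        if anchor_cuis is not None:
            # anchor = the query-term mention; the other fills the open slot
            if e1.cui in anchor_cuis:
                anchor, other = e1, e2
            else:
                anchor, other = e2, e1
        elif role == "AB":
            anchor, other = e1, e2
        else:
            anchor, other = e2, e1

        if role == "AB":
            ok = other.semtype in filter.linking_types
            checked = [other]
        else:
            # BC: the linking slot is `other` only under anchor_cuis
            # identification; positionally pair = (B, C).
            if anchor_cuis is not None:
                b_m, c_m = other, anchor
            else:
                b_m, c_m = e1, e2
            ok = (
                b_m.semtype in filter.linking_types
                and c_m.semtype in filter.target_types
            )
            checked = [b_m, c_m]

        if stats is not None:
            for m in checked:
                if m.semtype not in known_types:
                    stats["unknown_semtypes"].add(m.semtype)
        if not ok:
            if stats is not None:
                stats["dropped_semtype"] += 1
            continue

        if apply_general_to == "both":
            general_hit = e1.cui in general or e2.cui in general
        else:
            general_hit = checked[0].cui in general
        if general_hit:
            if stats is not None:
                stats["dropped_general"] += 1
            continue
        if stats is not None:
            stats["kept"] += 1
        yield sent
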