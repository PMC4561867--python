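"""Shared fixtures: hand-built sentences and small corpora."""

from __future__ import annotations

import pytest

from lbdkit.corpus import (
    AnnotatedSentence,
    DependencyEdge,
    EntityMention,
    Token,
)


def make_sentence(
    words,
    mentions,
    pair=("m1", "m2"),
    edges=None,
    sentence_id="s1",
    label="unlabeled",
    lemmas=None,
):
    """Build a sentence from (surface, pos) pairs; '.'/',' are punctuation.

    ``mentions`` is a list of (mention_id, start, end, cui, semtype).
    Default parse: right-branching chain i -> i+1.
    """
    tokens = []
    for i, (surface, pos) in enumerate(words):
        punct = pos == "PUNCT"
        lemma = (lemmas or {}).get(i, surface.lower())
        tokens.append(Token(i, surface, lemma, pos, punct))
    if edges is None:
        edges = [DependencyEdge(i, i + 1, "dep") for i in range(len(tokens) - 1)]
    else:
        edges = [DependencyEdge(*e) for e in edges]
    ms = [
        EntityMention(mid, start, end, cui, cui.lower(), semtype)
        for mid, start, end, cui, semtype in mentions
    ]
    sent = AnnotatedSentence(
        sentence_id=sentence_id,
        source_id="pm0",
        tokens=tokens,
        edges=edges,
        mentions=ms,
        pair=pair,
        label=label,
    )
    sent.canonicalize()
    sent.validate()
    return sent


@pytest.fixture
def quercetin_sentence():
    """The worked flavonoid example: two CUI-substituted entities.

    "Quercetin, one of the most representative C0596577 compounds, is
    involved in antiradical, C0003402, and prooxidant biological
    processes."
    """
    words = [
        ("Quercetin", "NN"), (",", "PUNCT"), ("one", "CD"), ("of", "IN"),
        ("the", "DT"), ("most", "RBS"), ("representative", "JJ"),
        ("C0596577", "NN"), ("compounds", "NNS"), (",", "PUNCT"),
        ("is", "VBZ"), ("involved", "VBN"), ("in", "IN"),
        ("antiradical", "JJ"), (",", "PUNCT"), ("C0003402", "NN"),
        (",", "PUNCT"), ("and", "CC"), ("prooxidant", "JJ"),
        ("biological", "JJ"), ("processes", "NNS"),
    ]
    return make_sentence(
        words,
        mentions=[
            ("m1", 7, 8, "C0596577", "Organic chemical"),
            ("m2", 15, 16, "C0003402", "Biologic function"),
        ],
    )


@pytest.fixture
def two_token_sentence():
    """Minimal parsed sentence: pair spans both tokens, one edge."""
    return make_sentence(
        [("C0001", "NN"), ("C0002", "NN")],
        mentions=[
            ("m1", 0, 1, "C0001", "Pathologic function"),
            ("m2", 1, 2, "C0002", "Cell function"),
        ],
        edges=[(0, 1, "nsubj")],
    )
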