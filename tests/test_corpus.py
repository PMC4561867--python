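"""Corpus model: I/O round-trips, general-concept list, type filtering."""

import json

import pytest

from lbdkit.corpus import (
    CorpusError,
    GeneralConceptList,
    PredicationTriple,
    SemanticTypeFilter,
    build_general_concept_list,
    filter_sentences,
    read_corpus,
    sentence_to_record,
    write_corpus,
)
from lbdkit.synth import GeneratorConfig, generate_corpus

from conftest import make_sentence


def _simple_sentence(sid="s1", b_semtype="Cell function", b_cui="C02",
                     a_cui="C01"):
    return make_sentence(
        [("C1", "NN"), ("causes", "VBZ"), ("C2", "NN"), (".", "PUNCT")],
        mentions=[
            ("m1", 0, 1, a_cui, "Disease or Syndrome"),
            ("m2", 2, 3, b_cui, b_semtype),
        ],
        sentence_id=sid,
        label="positive",
    )


class TestRoundTrip:
    def test_single_sentence_identity(self, tmp_path):
        path = tmp_path / "c.jsonl"
        write_corpus([_simple_sentence()], path)
        out = list(read_corpus(path))
        assert len(out) == 1
        assert out[0] == _simple_sentence()

    def test_synthetic_corpus_roundtrip_preserves_every_field(self, tmp_path):
        sents, _ = generate_corpus(GeneratorConfig(n_sentences=50, seed=1))
        path = tmp_path / "c.jsonl"
        write_corpus(sents, path)
        again = list(read_corpus(path))
        assert again == sents
        # byte-stable: rewriting the parsed stream reproduces the file
        path2 = tmp_path / "c2.jsonl"
        write_corpus(again, path2)
        assert path.read_bytes() == path2.read_bytes()

    def test_extra_fields_preserved_opaquely(self, tmp_path):
        sent = _simple_sentence()
        sent.extra["pub_year"] = 1984
        path = tmp_path / "c.jsonl"
        write_corpus([sent], path)
        assert list(read_corpus(path))[0].extra["pub_year"] == 1984

    def test_missing_mandatory_field_names_field_and_line(self, tmp_path):
        rec = sentence_to_record(_simple_sentence())
        del rec["tokens"]
        path = tmp_path / "bad.jsonl"
        path.write_text("\n" + json.dumps(rec) + "\n")
        with pytest.raises(CorpusError, match=r"tokens"):
            list(read_corpus(path))
        with pytest.raises(CorpusError, match=r":2"):
            list(read_corpus(path))

    def test_overlapping_pair_spans_skipped_with_warning(self, tmp_path):
        rec = sentence_to_record(_simple_sentence())
        rec["mentions"][1]["start"] = 0  # overlaps mention m1
        rec["mentions"][1]["end"] = 2
        path = tmp_path / "c.jsonl"
        with open(path, "w") as fh:
            fh.write(json.dumps(rec) + "\n")
            fh.write(json.dumps(sentence_to_record(_simple_sentence("s2"))) + "\n")
        with pytest.warns(UserWarning, match="spans overlap"):
            out = list(read_corpus(path))
        assert [s.sentence_id for s in out] == ["s2"]

    def test_pair_canonicalized_to_token_order(self):
        sent = _simple_sentence()
        sent.pair = ("m2", "m1")
        sent.canonicalize()
        assert sent.pair == ("m1", "m2")


class TestConllu:
    CONLLU = """\
# sent_id = x1
1\tC1\tc1\tNN\t_\t_\t2\tnsubj\t_\t_
2\tcauses\tcause\tVBZ\t_\t_\t0\troot\t_\t_
3\tC2\tc2\tNN\t_\t_\t2\tdobj\t_\t_
"""

    def test_conllu_with_standoff(self, tmp_path):
        cpath = tmp_path / "c.conllu"
        spath = tmp_path / "c.standoff.jsonl"
        cpath.write_text(self.CONLLU + "\n")
        spath.write_text(json.dumps({
            "sentence_id": "x1", "source_id": "pm1",
            "mentions": [
                {"mention_id": "m1", "start": 0, "end": 1, "cui": "C0X",
                 "semtype": "Disease or Syndrome"},
                {"mention_id": "m2", "start": 2, "end": 3, "cui": "C0Y",
                 "semtype": "Cell function"},
            ],
            "pair": ["m1", "m2"], "label": "positive",
        }) + "\n")
        (sent,) = list(read_corpus(cpath, format="conllu", standoff=spath))
        assert [t.lemma for t in sent.tokens] == ["c1", "cause", "c2"]
        assert {(e.governor, e.dependent, e.relation) for e in sent.edges} == {
            (1, 0, "nsubj"), (1, 2, "dobj")
        }
        assert sent.e2.cui == "C0Y"

    def test_conllu_requires_standoff(self, tmp_path):
        p = tmp_path / "c.conllu"
        p.write_text(self.CONLLU)
        with pytest.raises(CorpusError, match="standoff"):
            list(read_corpus(p, format="conllu"))


class TestGeneralConcepts:
    def test_single_isa_triple(self):
        got = build_general_concept_list([PredicationTriple("C1", "ISA", "C9")])
        assert got.concepts == {"C9"}

    def test_empty_input(self):
        assert len(build_general_concept_list([])) == 0

    def test_non_hierarchical_relations_ignored(self):
        triples = [
            PredicationTriple("C1", "ISA", "C10"),
            PredicationTriple("C2", "PART_OF", "C11"),
            PredicationTriple("C3", "LOCATION_OF", "C12"),
            PredicationTriple("C4", "ISA", "C13"),
            PredicationTriple("C5", "TREATS", "C14"),
            PredicationTriple("C6", "TREATS", "C15"),
        ]
        got = build_general_concept_list(triples)
        assert got.concepts == {"C10", "C11", "C12", "C13"}

    def test_order_independence(self):
        triples = [
            PredicationTriple(f"C{i}", rel, f"C{i + 100}")
            for i, rel in enumerate(["ISA", "PART_OF", "TREATS", "ISA"])
        ]
        fwd = build_general_concept_list(triples)
        rev = build_general_concept_list(reversed(triples))
        assert fwd.concepts == rev.concepts


class TestSemanticTypeFilter:
    def test_default_filter_sizes(self):
        flt = SemanticTypeFilter.default()
        assert len(flt.linking_types) == 9
        assert len(flt.target_types) == 5
        assert "Cell function" in flt.linking_types
        assert "Pharmacologic substance" in flt.target_types

    def test_allowed_linking_type_kept(self):
        flt = SemanticTypeFilter.default()
        kept = list(filter_sentences(
            [_simple_sentence(b_semtype="Cell function")],
            flt, GeneralConceptList(), role="AB",
        ))
        assert len(kept) == 1

    def test_general_concept_dropped(self):
        flt = SemanticTypeFilter.default()
        general = GeneralConceptList(frozenset({"C02"}))
        kept = list(filter_sentences(
            [_simple_sentence()], flt, general, role="AB"
        ))
        assert kept == []

    def test_hand_enumerated_mixed_batch(self):
        """12 sentences: 3 bad semtype, 2 general-listed, 1 both -> 6 kept."""
        flt = SemanticTypeFilter.default()
        general = GeneralConceptList(frozenset({"BAD1", "BAD2", "BAD3"}))
        sents = (
            [_simple_sentence(f"ok{i}") for i in range(6)]
            + [_simple_sentence(f"st{i}", b_semtype="Quantitative concept")
               for i in range(3)]
            + [_simple_sentence("g1", b_cui="BAD1"),
               _simple_sentence("g2", b_cui="BAD2")]
            + [_simple_sentence("both", b_semtype="Quantitative concept",
                                b_cui="BAD3")]
        )
        stats = {}
        kept = list(filter_sentences(sents, flt, general, role="AB",
                                     stats=stats))
        assert len(kept) == 6
        assert stats["dropped_semtype"] == 4  # includes the double violator
        assert stats["dropped_general"] == 2
        assert "Quantitative concept" in stats["unknown_semtypes"]

    def test_filter_idempotent_and_subset(self):
        flt = SemanticTypeFilter.default()
        general = GeneralConceptList(frozenset({"C0GEN"}))
        sents, _ = generate_corpus(GeneratorConfig(n_sentences=60, seed=2))
        once = list(filter_sentences(sents, flt, general, role="AB"))
        twice = list(filter_sentences(once, flt, general, role="AB"))
        assert twice == once
        ids = {s.sentence_id for s in sents}
        assert all(s.sentence_id in ids for s in once)

    def test_bc_role_checks_both_slots(self):
        flt = SemanticTypeFilter.default()
        sent = make_sentence(
            [("C2X", "NN"), ("inhibits", "VBZ"), ("C3X", "NN")],
            mentions=[("m1", 0, 1, "C2X", "Cell function"),
                      ("m2", 2, 3, "C3X", "Pharmacologic substance")],
        )
        assert list(filter_sentences([sent], flt, GeneralConceptList(),
                                     role="BC")) == [sent]
        bad = make_sentence(
            [("C2X", "NN"), ("inhibits", "VBZ"), ("C3X", "NN")],
            mentions=[("m1", 0, 1, "C2X", "Cell function"),
                      ("m2", 2, 3, "C3X", "Disease or Syndrome")],
        )
        assert list(filter_sentences([bad], flt, GeneralConceptList(),
                                     role="BC")) == []
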