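"""Corpus I/O: parsing, validation, round trips, strict evaluation."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemner.corpus_io import (
    AnnotatedEntity,
    Document,
    PRFResult,
    evaluate_strict,
    read_cemp_annotations,
    read_cemp_documents,
    write_predictions,
)


class TestReadDocuments:
    def test_single_record(self, tmp_path):
        p = tmp_path / "docs.tsv"
        p.write_text("D1\tA title\tAn abstract\n", encoding="utf-8")
        assert read_cemp_documents(p) == [Document("D1", "A title", "An abstract")]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "docs.tsv"
        p.write_text("", encoding="utf-8")
        assert read_cemp_documents(p) == []

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "docs.tsv"
        p.write_text("D1\ta\tb\nD1\tc\td\n", encoding="utf-8")
        with pytest.raises(ValueError, match="D1"):
            read_cemp_documents(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "docs.tsv"
        p.write_text("D1\ta\tb\nD2\tonly-two-cols\n", encoding="utf-8")
        with pytest.raises(ValueError, match="line 2"):
            read_cemp_documents(p)


class TestReadAnnotations:
    def test_substring_verified(self, tmp_path, doc_pair):
        docs, _ = doc_pair
        p = tmp_path / "ann.tsv"
        p.write_text("D1\tA\t3\t10\tacetone\t1.0\n", encoding="utf-8")
        (e,) = read_cemp_annotations(p, docs)
        assert (e.doc_id, e.field, e.start, e.end, e.text) == ("D1", "A", 3, 10, "acetone")

    def test_text_mismatch_rejected(self, tmp_path, doc_pair):
        docs, _ = doc_pair
        p = tmp_path / "ann.tsv"
        p.write_text("D1\tA\t3\t10\tbenzene\t1.0\n", encoding="utf-8")
        with pytest.raises(ValueError, match="D1"):
            read_cemp_annotations(p, docs)

    def test_unknown_doc_rejected(self, tmp_path, doc_pair):
        docs, _ = doc_pair
        p = tmp_path / "ann.tsv"
        p.write_text("D9\tA\t0\t2\tAn\t1.0\n", encoding="utf-8")
        with pytest.raises(ValueError, match="D9"):
            read_cemp_annotations(p, docs)

    def test_file_order_preserved(self, tmp_path, doc_pair):
        docs, ents = doc_pair
        p = tmp_path / "ann.tsv"
        write_predictions(ents, p)
        back = read_cemp_annotations(p, docs)
        assert [e.key for e in back] == [e.key for e in ents]


class TestWriteReadRoundTrip:
    def test_round_trip_fixed_point(self, tmp_path, doc_pair):
        docs, ents = doc_pair
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_predictions(ents, p1)
        once = read_cemp_annotations(p1, docs)
        write_predictions(once, p2)
        assert p1.read_text() == p2.read_text()

    def test_empty_list(self, tmp_path):
        p = tmp_path / "a.tsv"
        write_predictions([], p)
        assert p.read_text() == ""

    def test_overlap_rejected(self, tmp_path):
        ents = [
            AnnotatedEntity("D", "A", 0, 5, "abcde"),
            AnnotatedEntity("D", "A", 3, 8, "defgh"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            write_predictions(ents, tmp_path / "a.tsv")


def _ents(spans, doc="D", field="A"):
    return [
        AnnotatedEntity(doc, field, s, e, "x" * (e - s), 1.0) for s, e in spans
    ]


class TestEvaluateStrict:
    def test_identity_is_perfect(self, doc_pair):
        _, ents = doc_pair
        r = evaluate_strict(ents, ents)
        assert (r.precision, r.recall, r.f) == (1.0, 1.0, 1.0)

    def test_empty_predictions(self):
        r = evaluate_strict(_ents([(0, 5), (10, 14)]), [])
        assert (r.tp, r.fn, r.recall) == (0, 2, 0.0)

    def test_half_match(self):
        # gold {(0,5),(10,14)} vs pred {(0,5),(10,15)}: enumerated by hand
        r = evaluate_strict(_ents([(0, 5), (10, 14)]), _ents([(0, 5), (10, 15)]))
        assert (r.tp, r.fp, r.fn) == (1, 1, 1)
        assert r.f == pytest.approx(0.5)

    @given(
        spans=st.lists(
            st.tuples(st.integers(0, 50), st.integers(1, 10)), max_size=8
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_tp_symmetric_and_self_perfect(self, spans):
        gold = _ents([(s, s + w) for s, w in spans])
        self_eval = evaluate_strict(gold, gold)
        assert self_eval.fp == self_eval.fn == 0
        if gold:
            assert self_eval.f == 1.0
        other = _ents([(s + 1, s + w + 1) for s, w in spans[:3]])
        assert evaluate_strict(gold, other).tp == evaluate_strict(other, gold).tp


def test_prf_zero_denominators():
    r = PRFResult(tp=0, fp=0, fn=0)
    assert (r.precision, r.recall, r.f) == (0.0, 0.0, 0.0)
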