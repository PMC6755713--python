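"""Span decoding, ensemble arithmetic and overlap resolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemner.corpus_io import AnnotatedEntity
from chemner.decoder import (
    TagProbMatrix,
    ensemble_merge,
    extract_entities,
    remove_overlaps,
)

from conftest import brute_force_extract, onehot_matrix, random_prob_matrix


def matrix_for(P, text=None):
    n = len(P)
    text = text or "x" * n
    return TagProbMatrix(P, [(i, i + 1) for i in range(n)], "D", "A", text)


class TestExtractEntities:
    def test_one_hot_singleton(self):
        m = matrix_for(onehot_matrix(["O", "S", "O"]))
        (e,) = extract_entities(m, 0.5)
        assert (e.start, e.end, e.score) == (1, 2, 1.0)

    def test_all_outside_empty(self):
        assert extract_entities(matrix_for(onehot_matrix(["O"] * 5)), 0.5) == []

    def test_two_position_span_uses_b_and_e_only(self):
        P = np.zeros((2, 5))
        P[0] = [0.0, 0.1, 0.9, 0.0, 0.0]  # B = 0.9
        P[1] = [0.0, 0.2, 0.0, 0.0, 0.8]  # E = 0.8
        (e,) = extract_entities(matrix_for(P), 0.5)
        assert (e.start, e.end) == (0, 2)
        assert e.score == pytest.approx(0.8)

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(1, 13))
            P = random_prob_matrix(rng, n)
            for thr in (0.3, 0.5, 0.7):
                got = {
                    (e.start, e.end - 1, round(e.score, 9))
                    for e in extract_entities(matrix_for(P), thr)
                }
                assert got == brute_force_extract(P, thr)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            P = random_prob_matrix(rng, 10)
            m = matrix_for(P)
            lo = {(e.start, e.end) for e in extract_entities(m, 0.3)}
            hi = {(e.start, e.end) for e in extract_entities(m, 0.6)}
            assert hi <= lo

    def test_prefix_running_min_bounds_span_scores(self):
        # the quantity that justifies pruning: r_j = min(B[i], I[i+1..j])
        # never increases with j, and every span score is bounded by the
        # running min over its interior
        rng = np.random.default_rng(9)
        P = random_prob_matrix(rng, 8)
        m = matrix_for(P)
        score = {(e.start, e.end - 1): e.score for e in extract_entities(m, 0.0)}
        B, I = 2, 3
        for i in range(len(P)):
            running = P[i, B]
            for j in range(i + 1, len(P)):
                if (i, j) in score:
                    assert score[(i, j)] <= running + 1e-12
                new_running = min(running, P[j, I])
                assert new_running <= running + 1e-12
                running = new_running

    def test_character_offsets_and_text(self):
        text = "an acetone jar"
        P = onehot_matrix(
            ["O"] * 3 + ["B"] + ["I"] * 5 + ["E"] + ["O"] * 4
        )
        m = TagProbMatrix(P, [(i, i + 1) for i in range(len(text))], "D", "A", text)
        (e,) = extract_entities(m, 0.5)
        assert (e.start, e.end, e.text) == (3, 10, "acetone")


def _ent(start, end, score, doc="D", field="A"):
    return AnnotatedEntity(doc, field, start, end, "x" * (end - start), score)


class TestEnsembleMerge:
    def test_single_list_survives_at_096(self):
        (e,) = ensemble_merge([_ent(0, 5, 0.96)], [])
        assert e.score == pytest.approx(0.48)

    def test_single_list_dropped_at_094(self):
        assert ensemble_merge([_ent(0, 5, 0.94)], []) == []

    def test_both_lists_average(self):
        (e,) = ensemble_merge([_ent(0, 5, 0.6)], [_ent(0, 5, 0.5)])
        assert e.score == pytest.approx(0.55)

    def test_no_output_score_at_or_below_threshold(self):
        rng = np.random.default_rng(0)
        a = [_ent(i * 10, i * 10 + 5, float(s)) for i, s in enumerate(rng.random(20))]
        b = [_ent(i * 10 + 2, i * 10 + 7, float(s)) for i, s in enumerate(rng.random(20))]
        for e in ensemble_merge(a, b):
            assert e.score > 0.475

    def test_reduces_to_average_and_halving(self):
        rng = np.random.default_rng(1)
        a = {i: float(s) for i, s in enumerate(rng.random(10))}
        b = {i: float(s) for i, s in enumerate(rng.random(10), start=5)}
        la = [_ent(i * 10, i * 10 + 5, s) for i, s in a.items()]
        lb = [_ent(i * 10, i * 10 + 5, s) for i, s in b.items()]
        merged = {e.start // 10: e.score for e in ensemble_merge(la, lb, -1.0)}
        for i in set(a) | set(b):
            if i in a and i in b:
                assert merged[i] == pytest.approx((a[i] + b[i]) / 2)
            else:
                assert merged[i] == pytest.approx((a.get(i) or b.get(i)) / 2)


class TestRemoveOverlaps:
    def test_lower_scoring_overlap_discarded(self):
        kept = remove_overlaps([_ent(0, 5, 0.9), _ent(3, 8, 0.8)])
        assert [(e.start, e.end) for e in kept] == [(0, 5)]

    def test_disjoint_spans_all_kept(self):
        ents = [_ent(0, 5, 0.9), _ent(6, 8, 0.2)]
        assert len(remove_overlaps(ents)) == 2

    def test_three_mutual_overlaps_keep_max(self):
        ents = [_ent(0, 6, 0.5), _ent(2, 8, 0.9), _ent(4, 10, 0.7)]
        kept = remove_overlaps(ents)
        assert [(e.start, e.end) for e in kept] == [(2, 8)]

    def test_random_sets_nonoverlapping_and_maximal(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            ents = [
                _ent(s, s + 1 + int(rng.integers(0, 6)), float(rng.random()))
                for s in rng.integers(0, 30, size=rng.integers(1, 10))
            ]
            kept = remove_overlaps(ents)
            # no overlapping pair among kept
            for i, a in enumerate(kept):
                for b in kept[i + 1 :]:
                    if a.field == b.field and a.doc_id == b.doc_id:
                        assert a.end <= b.start or b.end <= a.start
            # every dropped entity overlaps some kept one
            kept_keys = {e.key for e in kept}
            for e in ents:
                if e.key not in kept_keys:
                    assert any(
                        not (e.end <= k.start or e.start >= k.end) for k in kept
                    )


class TestTagProbMatrixInvariants:
    def test_rows_must_sum_to_one(self):
        P = np.ones((2, 5))
        with pytest.raises(ValueError, match="sum"):
            matrix_for(P)

    def test_offsets_length_must_match(self):
        P = onehot_matrix(["O", "O"])
        with pytest.raises(ValueError):
            TagProbMatrix(P, [(0, 1)], "D", "A", "xx")
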