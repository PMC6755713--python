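"""Span decoding of SOBIE tag probabilities, ensembling, overlap removal.

A tagger emits, per position (token or character), a probability row over
the tags (S, O, B, I, E).  A candidate span scores the minimum of the tag
probabilities a correct tagging of that span would need: ``S[i]`` for a
single-position span, otherwise ``min(B[i], I[i+1..j-1], E[j])``.  Spans
scoring strictly above a threshold become entities with that score.

The search exploits antitonicity — extending a span can only lower its
score, since the minimum runs over a superset — to prune: a start position
is extended only while ``min(B[i], interior I)`` stays above the threshold.
This is output-equivalent to full enumeration (covered by an oracle test).

Two systems are ensembled by running both at a lowered threshold, summing
scores of spans found by both (keeping the single score otherwise), halving,
and applying a final threshold of 0.475 — low enough that a span only one
system can represent (e.g. one starting mid-token) survives on a strong
single score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_io import AnnotatedEntity
from .tokenizer import SOBIE_TAGS

__all__ = [
    "TagProbMatrix",
    "extract_entities",
    "ensemble_merge",
    "remove_overlaps",
    "DEFAULT_THRESHOLD",
    "ENSEMBLE_THRESHOLD",
    "ENSEMBLE_COMPONENT_THRESHOLD",
]

#: Per-system acceptance threshold.
DEFAULT_THRESHOLD = 0.5
#: Final threshold applied to halved/averaged ensemble scores.
ENSEMBLE_THRESHOLD = 0.475
#: Lowered threshold used when generating component lists for the ensemble.
ENSEMBLE_COMPONENT_THRESHOLD = 0.2

_S, _O, _B, _I, _E = range(5)  # column order == SOBIE_TAGS


@dataclass
class TagProbMatrix:
    """n positions x 5 tag probabilities, with source-text bookkeeping.

    ``offsets[k]`` is the (start, end) code-point span of position ``k`` in
    ``text`` — one token for the token tagger, one character for the
    character tagger.  Rows are ordered (S, O, B, I, E) and sum to 1.
    """

    probs: np.ndarray
    offsets: list[tuple[int, int]]
    doc_id: str = ""
    field: str = "A"
    text: str = ""

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs)
        if self.probs.size and self.probs.shape[1] != len(SOBIE_TAGS):
            raise ValueError("expected 5 probability columns")
        if len(self.offsets) != len(self.probs):
            raise ValueError("offsets/probs length mismatch")
        if self.probs.size:
            if (self.probs < -1e-6).any():
                raise ValueError("negative probabilities")
            if np.abs(self.probs.sum(axis=1) - 1.0).max() > 1e-4:
                raise ValueError("probability rows must sum to 1")

    def __len__(self) -> int:
        return len(self.probs)


def extract_entities(
    probs: TagProbMatrix, threshold: float = DEFAULT_THRESHOLD
) -> list[AnnotatedEntity]:
    """All spans scoring strictly above ``threshold``, possibly overlapping.

    Overlap resolution is a separate step (:func:`remove_overlaps`).
    """
    P = probs.probs
    n = len(P)
    out: list[AnnotatedEntity] = []

    def emit(i: int, j: int, score: float) -> None:
        start = probs.offsets[i][0]
        end = probs.offsets[j][1]
        out.append(
            AnnotatedEntity(
                probs.doc_id, probs.field, start, end,
                probs.text[start:end], float(score),
            )
        )

    for i in range(n):
        if P[i, _S] > threshold:
            emit(i, i, P[i, _S])
        running = P[i, _B]  # min(B[i], I[i+1..j-1]) so far
        if running <= threshold:
            continue
        for j in range(i + 1, n):
            score = min(running, P[j, _E])
            if score > threshold:
                emit(i, j, score)
            running = min(running, P[j, _I])
            if running <= threshold:
                break
    return out


def ensemble_merge(
    list_a: Sequence[AnnotatedEntity],
    list_b: Sequence[AnnotatedEntity],
    final_threshold: float = ENSEMBLE_THRESHOLD,
) -> list[AnnotatedEntity]:
    """Merge two component entity lists into ensemble entities.

    A span found by both systems gets (sA + sB) / 2; a span found by one
    gets s / 2.  Spans strictly above ``final_threshold`` survive.
    """
    merged: dict[tuple, AnnotatedEntity] = {}
    scores: dict[tuple, float] = {}
    for e in list(list_a) + list(list_b):
        if e.key in scores:
            scores[e.key] += e.score
        else:
            scores[e.key] = e.score
            merged[e.key] = e
    out = []
    for key, total in scores.items():
        s = total / 2.0
        if s > final_threshold:
            proto = merged[key]
            out.append(
                AnnotatedEntity(
                    proto.doc_id, proto.field, proto.start, proto.end,
                    proto.text, s,
                )
            )
    out.sort(key=lambda e: (e.doc_id, e.field, e.start, e.end))
    return out


def remove_overlaps(entities: Sequence[AnnotatedEntity]) -> list[AnnotatedEntity]:
    """Greedily discard lower-scoring entities that overlap kept ones.

    Priority: higher score, then earlier start, then longer span.  Applied
    per (doc_id, field) group; the result contains no overlapping pair and
    every discarded span overlaps some kept higher-priority span.
    """
    groups: dict[tuple[str, str], list[AnnotatedEntity]] = {}
    for e in entities:
        groups.setdefault((e.doc_id, e.field), []).append(e)
    kept: list[AnnotatedEntity] = []
    for group in groups.values():
        group.sort(key=lambda e: (-e.score, e.start, -(e.end - e.start)))
        chosen: list[AnnotatedEntity] = []
        for e in group:
            if all(e.end <= k.start or e.start >= k.end for k in chosen):
                chosen.append(e)
        kept.extend(chosen)
    kept.sort(key=lambda e: (e.doc_id, e.field, e.start, e.end))
    return kept
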