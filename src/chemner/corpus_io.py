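"""Reading/writing annotated corpora and strict span-level evaluation.

The corpus unit is a patent-style record: a document id, a title and an
abstract.  Annotations are character-offset entity spans against either the
title (field ``T``) or the abstract (field ``A``).  Offsets are 0-based,
half-open, counted in Unicode code points.

File dialects (UTF-8, tab-separated):

* documents:   ``doc_id<TAB>title<TAB>abstract``
* annotations: ``doc_id<TAB>field<TAB>start<TAB>end<TAB>text<TAB>score``
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Document",
    "AnnotatedEntity",
    "PRFResult",
    "read_cemp_documents",
    "read_cemp_annotations",
    "write_predictions",
    "evaluate_strict",
]


@dataclass(frozen=True)
class Document:
    """One title+abstract record."""

    doc_id: str
    title: str
    abstract: str

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")

    def field_text(self, field: str) -> str:
        if field == "T":
            return self.title
        if field == "A":
            return self.abstract
        raise ValueError(f"unknown field {field!r} (expected 'T' or 'A')")


@dataclass(frozen=True)
class AnnotatedEntity:
    """A scored entity span within one field of one document.

    ``start``/``end`` are 0-based code-point offsets, end exclusive.  Gold
    annotations carry score 1.0; predictions carry the decoder's span score.
    """

    doc_id: str
    field: str  # 'T' or 'A'
    start: int
    end: int
    text: str
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.field not in ("T", "A"):
            raise ValueError(f"field must be 'T' or 'A', got {self.field!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"bad span [{self.start}, {self.end}) for doc {self.doc_id}"
            )
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")

    @property
    def key(self) -> tuple[str, str, int, int]:
        """Identity used by strict matching and ensemble merging."""
        return (self.doc_id, self.field, self.start, self.end)


@dataclass(frozen=True)
class PRFResult:
    """Strict span-level precision/recall/F counts and fractions."""

    tp: int
    fp: int
    fn: int
    precision: float = dc_field(init=False, default=0.0)
    recall: float = dc_field(init=False, default=0.0)
    f: float = dc_field(init=False, default=0.0)

    def __post_init__(self) -> None:
        p = self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0
        r = self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0
        f = 2 * p * r / (p + r) if (p + r) else 0.0
        object.__setattr__(self, "precision", p)
        object.__setattr__(self, "recall", r)
        object.__setattr__(self, "f", f)


def read_cemp_documents(path: str | Path) -> list[Document]:
    """Read a tab-separated document file, one record per line.

    Raises ``ValueError`` on a malformed line (naming the line number) or a
    duplicated document id (naming the id).
    """
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 tab-separated columns, "
                    f"got {len(parts)}"
                )
            doc_id, title, abstract = parts
            if doc_id in seen:
                raise ValueError(f"{path}: duplicated doc_id {doc_id!r}")
            seen.add(doc_id)
            docs.append(Document(doc_id, title, abstract))
    return docs


def read_cemp_annotations(
    path: str | Path, documents: Sequence[Document]
) -> list[AnnotatedEntity]:
    """Read an annotation/prediction file and validate spans against documents.

    Every returned entity satisfies the substring invariant: its text equals
    the ``[start, end)`` slice of the referenced field.
    """
    by_id = {d.doc_id: d for d in documents}
    out: list[AnnotatedEntity] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 5:
                doc_id, field, start_s, end_s, text = parts
                score = 1.0
            elif len(parts) == 6:
                doc_id, field, start_s, end_s, text, score_s = parts
                score = float(score_s)
            else:
                raise ValueError(
                    f"{path}: line {lineno}: expected 5 or 6 columns, "
                    f"got {len(parts)}"
                )
            if doc_id not in by_id:
                raise ValueError(f"{path}: line {lineno}: unknown doc_id {doc_id!r}")
            start, end = int(start_s), int(end_s)
            source = by_id[doc_id].field_text(field)
            if not (0 <= start < end <= len(source)):
                raise ValueError(
                    f"{path}: line {lineno}: span [{start}, {end}) out of range "
                    f"for doc {doc_id!r} field {field}"
                )
            if source[start:end] != text:
                raise ValueError(
                    f"{path}: line {lineno}: text mismatch for doc {doc_id!r} "
                    f"[{start}, {end}): annotation {text!r} vs "
                    f"document {source[start:end]!r}"
                )
            out.append(AnnotatedEntity(doc_id, field, start, end, text, score))
    return out


def _overlapping_pair(
    entities: Iterable[AnnotatedEntity],
) -> tuple[AnnotatedEntity, AnnotatedEntity] | None:
    groups: dict[tuple[str, str], list[AnnotatedEntity]] = {}
    for e in entities:
        groups.setdefault((e.doc_id, e.field), []).append(e)
    for group in groups.values():
        group = sorted(group, key=lambda e: (e.start, e.end))
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                return a, b
    return None


def write_predictions(
    entities: Sequence[AnnotatedEntity], path: str | Path
) -> None:
    """Write entities in the annotation dialect; scores with fixed precision.

    Overlapping entities within one (doc_id, field) are rejected; run the
    decoder's ``remove_overlaps`` first.
    """
    clash = _overlapping_pair(entities)
    if clash is not None:
        a, b = clash
        raise ValueError(
            f"overlapping entities for doc {a.doc_id!r} field {a.field}: "
            f"[{a.start}, {a.end}) and [{b.start}, {b.end})"
        )
    with open(path, "w", encoding="utf-8") as fh:
        for e in entities:
            fh.write(
                f"{e.doc_id}\t{e.field}\t{e.start}\t{e.end}\t{e.text}"
                f"\t{e.score:.6f}\n"
            )


def evaluate_strict(
    gold: Sequence[AnnotatedEntity], pred: Sequence[AnnotatedEntity]
) -> PRFResult:
    """Strict span-level evaluation.

    A prediction is a true positive iff its (doc_id, field, start, end)
    exactly matches a gold span; each gold span matches at most one
    prediction.
    """
    gold_keys = {e.key for e in gold}
    pred_keys = {e.key for e in pred}
    tp = len(gold_keys & pred_keys)
    return PRFResult(tp=tp, fp=len(pred_keys) - tp, fn=len(gold_keys) - tp)
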