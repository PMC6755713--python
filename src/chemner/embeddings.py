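"""Vocabulary construction and GloVe-format embedding loading.

The token tagger maps each token to a row of an embedding matrix.  The
vocabulary keeps tokens occurring more than ``min_count`` times in the
training corpus (default: more than two); everything else shares a single
unknown-token row.  Rows are initialised from a plain-text embedding file
("word v1 v2 ... vd" per line) where available and zeros otherwise; the
unknown row is zeros.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Vocabulary",
    "EmbeddingTable",
    "build_vocab",
    "load_embeddings_text",
    "init_embedding_matrix",
]


@dataclass
class Vocabulary:
    """Dense token -> index map with a designated unknown index."""

    index: dict[str, int]
    unknown_index: int
    min_count: int

    def __len__(self) -> int:
        return len(self.index) + 1  # + unknown row

    def lookup(self, token: str) -> int:
        return self.index.get(token, self.unknown_index)

    def encode(self, tokens: Sequence[str]) -> np.ndarray:
        return np.array([self.lookup(t) for t in tokens], dtype=np.int64)


@dataclass
class EmbeddingTable:
    """vocab-size x dimension matrix (unknown row included)."""

    dimension: int
    rows: np.ndarray

    def __post_init__(self) -> None:
        if self.rows.ndim != 2 or self.rows.shape[1] != self.dimension:
            raise ValueError("rows shape inconsistent with dimension")


def build_vocab(
    tokenised_corpus: Iterable[Sequence[str]], min_count: int = 2
) -> Vocabulary:
    """Build a vocabulary of tokens occurring strictly more than
    ``min_count`` times; all others map to the unknown index."""
    counts: Counter[str] = Counter()
    for sent in tokenised_corpus:
        counts.update(sent)
    kept = sorted(t for t, c in counts.items() if c > min_count)
    index = {t: i for i, t in enumerate(kept)}
    return Vocabulary(index=index, unknown_index=len(kept), min_count=min_count)


def load_embeddings_text(path: str | Path) -> dict[str, np.ndarray]:
    """Load a GloVe-style plain-text embedding file (no header line).

    All vectors must share one dimension; a ragged line raises ``ValueError``
    with its line number; a duplicated token keeps the first occurrence and
    warns.
    """
    table: dict[str, np.ndarray] = {}
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split()
            if not parts:
                continue
            token, values = parts[0], parts[1:]
            if dim is None:
                dim = len(values)
                if dim == 0:
                    raise ValueError(f"{path}: line {lineno}: no vector values")
            elif len(values) != dim:
                raise ValueError(
                    f"{path}: line {lineno}: expected {dim} values, "
                    f"got {len(values)}"
                )
            if token in table:
                warnings.warn(f"duplicate embedding token {token!r}; keeping first")
                continue
            table[token] = np.asarray(values, dtype=np.float32)
    return table


def init_embedding_matrix(
    vocab: Vocabulary,
    pretrained: Mapping[str, np.ndarray],
    dimension: int | None = None,
) -> EmbeddingTable:
    """Initialise the embedding matrix for a vocabulary.

    A token's row is its pretrained vector when present (falling back to the
    lowercased form, which maximises coverage of case-normalised embedding
    files), otherwise zeros.  The unknown row is zeros.
    """
    if dimension is None:
        if pretrained:
            dimension = len(next(iter(pretrained.values())))
        else:
            raise ValueError("dimension required when pretrained map is empty")
    rows = np.zeros((len(vocab), dimension), dtype=np.float32)
    for token, i in vocab.index.items():
        vec = pretrained.get(token)
        if vec is None:
            vec = pretrained.get(token.lower())
        if vec is not None:
            if len(vec) != dimension:
                raise ValueError(
                    f"embedding for {token!r} has dimension {len(vec)}, "
                    f"expected {dimension}"
                )
            rows[i] = vec
    return EmbeddingTable(dimension=dimension, rows=rows)
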