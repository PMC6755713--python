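"""Shared fixtures and oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from chemner.corpus_io import AnnotatedEntity, Document
from chemner.synthetic import GeneratorParams, generate_corpus


def brute_force_extract(P: np.ndarray, threshold: float) -> set[tuple[int, int, float]]:
    """Independent span-extraction oracle: enumerate every [i, j] span and
    apply the min-over-tags rule directly.  Positions inclusive."""
    S, O, B, I, E = range(5)
    found = set()
    n = len(P)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                score = P[i, S]
            else:
                score = min(
                    [P[i, B]] + [P[k, I] for k in range(i + 1, j)] + [P[j, E]]
                )
            if score > threshold:
                found.add((i, j, round(float(score), 9)))
    return found


def random_prob_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Row-stochastic matrix with a mix of confident and diffuse rows."""
    alpha = rng.choice([0.2, 0.6, 2.0])
    return rng.dirichlet(np.full(5, alpha), size=n).astype(np.float64)


def onehot_matrix(tags: list[str]) -> np.ndarray:
    from chemner.tokenizer import SOBIE_TAGS

    P = np.zeros((len(tags), 5))
    for i, t in enumerate(tags):
        P[i, SOBIE_TAGS.index(t)] = 1.0
    return P


def random_nonoverlapping_spans(
    rng: np.random.Generator, length: int, max_spans: int = 4
) -> list[tuple[int, int]]:
    """Random disjoint, boundary-sorted [start, end) spans within [0, length)."""
    spans = []
    pos = 0
    for _ in range(max_spans):
        if pos >= length - 1:
            break
        start = pos + int(rng.integers(0, min(4, length - pos)))
        if start >= length:
            break
        end = start + 1 + int(rng.integers(0, min(4, length - start)))
        end = min(end, length)
        if end > start:
            spans.append((start, end))
            pos = end + 1
    return spans


@pytest.fixture(scope="session")
def tiny_corpus():
    """A 60-document synthetic corpus shared by fast tests."""
    return generate_corpus(GeneratorParams(n_documents=60, seed=11))


@pytest.fixture()
def doc_pair():
    docs = [
        Document("D1", "A title", "An acetone jar"),
        Document("D2", "Salt study", "Mix NaCl with water"),
    ]
    ents = [
        AnnotatedEntity("D1", "A", 3, 10, "acetone"),
        AnnotatedEntity("D2", "A", 4, 8, "NaCl"),
        AnnotatedEntity("D2", "T", 0, 4, "Salt"),
    ]
    return docs, ents
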