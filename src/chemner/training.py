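"""Epoch/mini-batch training loop shared by both taggers.

Mini-batches are drawn from groups of sequences of exactly the same length,
so no padding or masking is ever needed.  During the first
``curriculum_epochs`` epochs the length groups are visited shortest first
(length curriculum); afterwards mini-batch order is shuffled every epoch.

After every epoch the model is checkpointed (in memory) and strict
entity-level F on the held-out set is computed by decoding at threshold 0.5
— the same decoding used at final inference — and the checkpoint with the
best F is restored at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .corpus_io import AnnotatedEntity, PRFResult, evaluate_strict
from .decoder import DEFAULT_THRESHOLD, TagProbMatrix, extract_entities, remove_overlaps
from .nn import RMSProp

__all__ = ["TaggedSequence", "TrainResult", "train_tagger", "predict_sequences"]


@dataclass
class TaggedSequence:
    """One network input sequence with its targets and source bookkeeping.

    ``inputs`` holds one array per network input, each with leading axis of
    length T (token/char positions).  ``onehot`` is the (T, 5) SOBIE target.
    ``gold`` lists this field's gold entities (for held-out evaluation).
    """

    inputs: tuple[np.ndarray, ...]
    onehot: np.ndarray | None
    doc_id: str
    field: str
    text: str
    offsets: list[tuple[int, int]]
    gold: list[AnnotatedEntity] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.offsets)


@dataclass
class TrainResult:
    history: list[dict]
    best_epoch: int  # 1-based

    @property
    def best_f(self) -> float:
        return self.history[self.best_epoch - 1]["f"]


def _length_groups(seqs: Sequence[TaggedSequence]) -> dict[int, list[int]]:
    groups: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        groups.setdefault(len(s), []).append(i)
    return groups


def _stack_batch(
    seqs: Sequence[TaggedSequence], idx: Sequence[int]
) -> tuple[tuple[np.ndarray, ...], np.ndarray]:
    n_inputs = len(seqs[idx[0]].inputs)
    xs = tuple(
        np.stack([seqs[i].inputs[k] for i in idx]) for k in range(n_inputs)
    )
    y = np.stack([seqs[i].onehot for i in idx])
    return xs, y


def predict_sequences(
    network, seqs: Sequence[TaggedSequence], batch_size: int = 64
) -> list[TagProbMatrix]:
    """Batched inference (grouped by length); one TagProbMatrix per sequence."""
    out: list[TagProbMatrix | None] = [None] * len(seqs)
    for _, idx in sorted(_length_groups(seqs).items()):
        for k in range(0, len(idx), batch_size):
            chunk = idx[k : k + batch_size]
            xs = tuple(
                np.stack([seqs[i].inputs[j] for i in chunk])
                for j in range(len(seqs[chunk[0]].inputs))
            )
            probs = network.predict_probs_batch(xs)
            for row, i in enumerate(chunk):
                s = seqs[i]
                out[i] = TagProbMatrix(
                    probs[row], s.offsets, s.doc_id, s.field, s.text
                )
    return [m for m in out if m is not None]


def evaluate_heldout(
    network,
    heldout: Sequence[TaggedSequence],
    threshold: float = DEFAULT_THRESHOLD,
    batch_size: int = 64,
) -> PRFResult:
    """Strict entity-level F of decoded predictions against gold spans."""
    pred: list[AnnotatedEntity] = []
    for m in predict_sequences(network, heldout, batch_size):
        pred.extend(extract_entities(m, threshold))
    pred = remove_overlaps(pred)
    gold = [e for s in heldout for e in s.gold]
    return evaluate_strict(gold, pred)


def train_tagger(
    network,
    train_set: Sequence[TaggedSequence],
    heldout_set: Sequence[TaggedSequence],
    epochs: int,
    curriculum_epochs: int = 0,
    batch_size: int = 32,
    lr: float = 1e-3,
    seed: int = 42,
    threshold: float = DEFAULT_THRESHOLD,
    interleave: Callable[[list], None] | None = None,
    step_log: list | None = None,
    log_path: str | Path | None = None,
    optimizer: RMSProp | None = None,
) -> TrainResult:
    """Train a tagger network, returning it restored to its best epoch.

    ``interleave`` (used by transfer-learning schedules) is called before
    every main mini-batch and may run auxiliary mini-batches, appending its
    own labels to ``step_log``; the loop itself appends ``"M"`` per main
    batch.
    """
    if not heldout_set:
        raise ValueError("heldout set must be non-empty")
    if not train_set:
        raise ValueError("train set must be non-empty")
    opt = optimizer if optimizer is not None else RMSProp(lr=lr)
    rng = np.random.default_rng(seed)
    history: list[dict] = []
    checkpoints: list[list[np.ndarray]] = []

    for epoch in range(1, epochs + 1):
        groups = _length_groups(train_set)
        batches: list[tuple[int, list[int]]] = []
        for length in sorted(groups):
            idx = groups[length].copy()
            rng.shuffle(idx)
            for k in range(0, len(idx), batch_size):
                batches.append((length, idx[k : k + batch_size]))
        if epoch > curriculum_epochs:
            rng.shuffle(batches)
        # else: batches already in ascending length order (shortest first)

        total_loss, n_batches = 0.0, 0
        for _, idx in batches:
            if interleave is not None:
                interleave(step_log)  # auxiliary mini-batches come first
            xs, y = _stack_batch(train_set, idx)
            loss = network.train_batch(xs, y)
            opt.step(network.params())
            total_loss += loss
            n_batches += 1
            if step_log is not None:
                step_log.append("M")

        prf = evaluate_heldout(network, heldout_set, threshold)
        history.append(
            {
                "epoch": epoch,
                "loss": total_loss / max(n_batches, 1),
                "tp": prf.tp,
                "fp": prf.fp,
                "fn": prf.fn,
                "precision": prf.precision,
                "recall": prf.recall,
                "f": prf.f,
            }
        )
        checkpoints.append([p.value.copy() for p in network.params()])

    best = int(np.argmax([h["f"] for h in history]))  # earliest on ties
    for p, w in zip(network.params(), checkpoints[best]):
        p.value[...] = w

    if log_path is not None:
        with open(log_path, "w", encoding="utf-8") as fh:
            fh.write("epoch\tloss\tprecision\trecall\tf\n")
            for h in history:
                fh.write(
                    f"{h['epoch']}\t{h['loss']:.6f}\t{h['precision']:.6f}"
                    f"\t{h['recall']:.6f}\t{h['f']:.6f}\n"
                )
    return TrainResult(history=history, best_epoch=best + 1)
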