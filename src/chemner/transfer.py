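"""Transfer learning for the character tagger, with interleaving schedules.

Two auxiliary tasks pre-train (or co-train) the shared layers of the
minimalist network:

* **Predictive transfer** — a character language model: the forward LSTM
  predicts the next character, the reversed LSTM the previous one, each
  through its own 91-way softmax head.  Trained on a plain-text corpus,
  each line used once.
* **Dictionary transfer** — whole-word classification: a word's character
  sequence runs through the full recurrent stack, is max-pooled over
  positions, and a 3-way sigmoid head predicts membership in the
  chemical-name list, the element list and the English dictionary.

Each task can run entirely before main training ("at start") or alternate
with it mini-batch by mini-batch ("interleaved") until its data is
exhausted.  Interleaving the dictionary task — and pairing it with
predictive transfer — is the mitigation for negative transfer: dictionary
pre-training alone can hurt the main task.  When both tasks run at the
start, the predictive-first, dictionary-first and mutually-interleaved
orderings are all supported.

The auxiliary networks share layer *objects* with the main network, so a
transfer step updates the very parameters main training continues from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

from .corpus_io import AnnotatedEntity, Document
from .featurizer import Lexicon
from .minimalist_model import (
    CharInventory,
    MinimalistConfig,
    MinimalistNetwork,
    MinimalistTagger,
)
from .nn import Dense, GlobalMaxPool, RMSProp, TimeDense, sigmoid_bce, softmax_xent
from .training import TrainResult

__all__ = [
    "shift_targets",
    "PredictiveTransferNetwork",
    "DictionaryTransferNetwork",
    "build_predictive_transfer_network",
    "build_dictionary_transfer_network",
    "word_membership_labels",
    "ScheduleSpec",
    "VALID_SCHEDULES",
    "ScheduleResources",
    "run_training_schedule",
    "train_predictive",
    "train_dictionary",
]


def shift_targets(
    char_indices: np.ndarray, n_classes: int = 91
) -> tuple[np.ndarray, np.ndarray]:
    """One-hot next-character and previous-character targets.

    ``left[i]`` encodes ``char[i+1]`` (predict the next character from the
    forward pass), ``right[i]`` encodes ``char[i-1]``.  Boundary positions
    are all-zero rows — a padding "class" excluded from the loss (masks are
    the row sums).
    """
    ids = np.asarray(char_indices)
    T = len(ids)
    if T < 2:
        raise ValueError("need at least 2 characters to build shifted targets")
    left = np.zeros((T, n_classes), dtype=np.float32)
    right = np.zeros((T, n_classes), dtype=np.float32)
    left[np.arange(T - 1), ids[1:]] = 1.0
    right[np.arange(1, T), ids[:-1]] = 1.0
    return left, right


class PredictiveTransferNetwork:
    """Character-LM heads over the main network's shared embed/ml1/ml2."""

    def __init__(self, main: MinimalistNetwork) -> None:
        self.main = main
        self.embed, self.ml1, self.ml2 = main.embed, main.ml1, main.ml2
        n = main.inventory.size
        rng = np.random.default_rng(main.config.seed + 101)
        u = main.config.lstm_units
        self.md2 = TimeDense(u, n, rng, activation="softmax")
        self.md3 = TimeDense(u, n, rng, activation="softmax")
        self.n_classes = n

    def params(self):
        return (
            self.embed.params() + self.ml1.params() + self.ml2.params()
            + self.md2.params() + self.md3.params()
        )

    def forward(self, ids: np.ndarray, train: bool = False):
        x = self.embed.forward(ids, train)
        rng = self.main._rng
        h1 = self.ml1.forward(x, train, rng)
        h2 = self.ml2.forward(x, train, rng)
        return self.md2.forward(h1, train), self.md3.forward(h2, train)

    def train_batch(self, ids: np.ndarray) -> float:
        B, T = ids.shape
        left = np.zeros((B, T, self.n_classes), dtype=np.float32)
        right = np.zeros_like(left)
        for b in range(B):
            left[b], right[b] = shift_targets(ids[b], self.n_classes)
        p_left, p_right = self.forward(ids, train=True)
        loss_l, dz_l = softmax_xent(p_left, left, mask=left.sum(axis=2))
        loss_r, dz_r = softmax_xent(p_right, right, mask=right.sum(axis=2))
        d1 = self.md2.backward(dz_l)
        d2 = self.md3.backward(dz_r)
        dx = self.ml1.backward(d1) + self.ml2.backward(d2)
        self.embed.backward(dx)
        return loss_l + loss_r


class DictionaryTransferNetwork:
    """Word-membership head over the main network's full recurrent stack."""

    def __init__(self, main: MinimalistNetwork) -> None:
        self.main = main
        rng = np.random.default_rng(main.config.seed + 202)
        self.pool = GlobalMaxPool()
        self.md4 = Dense(2 * main.config.bilstm_units, 3, rng, activation="sigmoid")

    def params(self):
        m = self.main
        return (
            m.embed.params() + m.ml1.params() + m.ml2.params()
            + m.mb1.params() + m.mb2.params() + self.md4.params()
        )

    def forward(self, ids: np.ndarray, train: bool = False) -> np.ndarray:
        m = self.main
        rng = m._rng
        x = m.embed.forward(ids, train)
        h1 = m.ml1.forward(x, train, rng)
        h2 = m.ml2.forward(x, train, rng)
        mm = np.concatenate([h1, h2], axis=2)
        mm = m.mm1_drop.forward(mm, train, rng)
        b1 = m.mb1.forward(mm, train, rng)
        b2 = m.mb2.forward(b1, train, rng)
        return self.md4.forward(self.pool.forward(b2, train), train)

    def train_batch(self, ids: np.ndarray, labels: np.ndarray) -> float:
        m = self.main
        probs = self.forward(ids, train=True)
        loss, dz = sigmoid_bce(probs, labels)
        d = self.pool.backward(self.md4.backward(dz))
        d = m.mb2.backward(d)
        d = m.mb1.backward(d)
        d = m.mm1_drop.backward(d)
        u = m.config.lstm_units
        dx = m.ml1.backward(d[:, :, :u]) + m.ml2.backward(d[:, :, u:])
        m.embed.backward(dx)
        return loss


def build_predictive_transfer_network(main: MinimalistNetwork) -> PredictiveTransferNetwork:
    """Language-model heads sharing the main network's embed/ml1/ml2."""
    return PredictiveTransferNetwork(main)


def build_dictionary_transfer_network(main: MinimalistNetwork) -> DictionaryTransferNetwork:
    """Membership head sharing the main network's full recurrent stack."""
    return DictionaryTransferNetwork(main)


def word_membership_labels(
    word: str, lexicons: Sequence[Lexicon]
) -> np.ndarray:
    """3-bit membership vector: (chemical list, element list, English)."""
    if len(lexicons) != 3:
        raise ValueError("expected exactly 3 lexicons (chemical, element, English)")
    return np.array([1.0 if word in lex else 0.0 for lex in lexicons], dtype=np.float32)


# ---------------------------------------------------------------------------
# Schedules

_PRED_MODES = ("none", "at_start", "interleaved")
_DICT_MODES = (
    "none", "at_start", "after_predictive", "before_predictive",
    "interleaved_with_predictive", "interleaved",
)

#: The 11 supported (predictive, dictionary) combinations.
VALID_SCHEDULES: frozenset[tuple[str, str]] = frozenset(
    [
        ("none", "none"),
        ("none", "at_start"),
        ("none", "interleaved"),
        ("at_start", "none"),
        ("at_start", "after_predictive"),
        ("at_start", "before_predictive"),
        ("at_start", "interleaved_with_predictive"),
        ("at_start", "interleaved"),
        ("interleaved", "none"),
        ("interleaved", "at_start"),
        ("interleaved", "interleaved"),
    ]
)


@dataclass(frozen=True)
class ScheduleSpec:
    """A (predictive, dictionary) transfer schedule combination."""

    predictive: str = "none"
    dictionary: str = "none"

    def __post_init__(self) -> None:
        if (self.predictive, self.dictionary) not in VALID_SCHEDULES:
            valid = ", ".join(f"{p}/{d}" for p, d in sorted(VALID_SCHEDULES))
            raise ValueError(
                f"invalid schedule {self.predictive}/{self.dictionary}; "
                f"valid combinations: {valid}"
            )


@dataclass
class ScheduleResources:
    """Everything a schedule needs: data, lexicons, configuration."""

    config: MinimalistConfig
    train_docs: Sequence[Document]
    heldout_docs: Sequence[Document]
    entities: Sequence[AnnotatedEntity]
    transfer_lines: Sequence[str] = ()
    lexicons: Sequence[Lexicon] = ()  # chemical, element, English
    dict_words: Sequence[str] | None = None  # default: union of lexicon terms
    transfer_batch_size: int = 32
    inventory: CharInventory = field(default_factory=CharInventory)


def _predictive_batches(
    lines: Sequence[str], inventory: CharInventory, batch_size: int, max_len: int
) -> list[np.ndarray]:
    """Equal-length mini-batches of encoded corpus lines (each line once)."""
    by_len: dict[int, list[np.ndarray]] = {}
    for line in lines:
        line = line[:max_len]
        if len(line) < 2:
            continue
        by_len.setdefault(len(line), []).append(inventory.encode(line))
    batches = []
    for length in sorted(by_len):
        seqs = by_len[length]
        for k in range(0, len(seqs), batch_size):
            batches.append(np.stack(seqs[k : k + batch_size]))
    return batches


def _dictionary_batches(
    words: Sequence[str],
    lexicons: Sequence[Lexicon],
    inventory: CharInventory,
    batch_size: int,
    max_len: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    import warnings

    by_len: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
    for w in words:
        if not w:
            continue
        if len(w) > max_len:
            warnings.warn(f"dictionary word longer than max_len skipped: {w[:30]}...")
            continue
        by_len.setdefault(len(w), []).append(
            (inventory.encode(w), word_membership_labels(w, lexicons))
        )
    batches = []
    for length in sorted(by_len):
        pairs = by_len[length]
        for k in range(0, len(pairs), batch_size):
            chunk = pairs[k : k + batch_size]
            batches.append(
                (np.stack([c[0] for c in chunk]), np.stack([c[1] for c in chunk]))
            )
    return batches


def train_predictive(
    corpus_lines: Sequence[str],
    ptn: PredictiveTransferNetwork,
    optimizer: RMSProp,
    batch_size: int = 32,
    step_log: list | None = None,
) -> int:
    """One full pass of predictive transfer (the "at start" block)."""
    if not corpus_lines:
        raise ValueError("predictive transfer corpus is empty")
    batches = _predictive_batches(
        corpus_lines, ptn.main.inventory, batch_size, ptn.main.config.max_len
    )
    for ids in batches:
        ptn.train_batch(ids)
        optimizer.step(ptn.params())
        if step_log is not None:
            step_log.append("P")
    return len(batches)


def train_dictionary(
    words: Sequence[str],
    lexicons: Sequence[Lexicon],
    dtn: DictionaryTransferNetwork,
    optimizer: RMSProp,
    batch_size: int = 32,
    step_log: list | None = None,
) -> int:
    """One full pass of dictionary transfer (the "at start" block)."""
    if not words:
        raise ValueError("dictionary transfer word list is empty")
    batches = _dictionary_batches(
        words, lexicons, dtn.main.inventory, batch_size, dtn.main.config.max_len
    )
    for ids, labels in batches:
        dtn.train_batch(ids, labels)
        optimizer.step(dtn.params())
        if step_log is not None:
            step_log.append("D")
    return len(batches)


def run_training_schedule(
    spec: ScheduleSpec, resources: ScheduleResources
) -> tuple[MinimalistTagger, TrainResult, list[str]]:
    """Execute a transfer schedule and main training; returns the tagger,
    the main-training result and the step log ('P'/'D'/'M' per mini-batch).
    """
    if (spec.predictive, spec.dictionary) not in VALID_SCHEDULES:
        raise ValueError("invalid schedule")  # unreachable via ScheduleSpec
    cfg = resources.config
    network = MinimalistNetwork(cfg, resources.inventory)
    tagger = MinimalistTagger(cfg, resources.inventory)
    optimizer = RMSProp(lr=cfg.learning_rate)
    step_log: list[str] = []

    need_pred = spec.predictive != "none"
    need_dict = spec.dictionary != "none"
    ptn = PredictiveTransferNetwork(network) if need_pred else None
    dtn = DictionaryTransferNetwork(network) if need_dict else None

    pred_batches: list[np.ndarray] = []
    if need_pred:
        if not resources.transfer_lines:
            raise ValueError("schedule requires a transfer corpus")
        pred_batches = _predictive_batches(
            resources.transfer_lines, resources.inventory,
            resources.transfer_batch_size, cfg.max_len,
        )
    dict_batches: list[tuple[np.ndarray, np.ndarray]] = []
    if need_dict:
        words = resources.dict_words
        if words is None:
            words = sorted(set().union(*(lex.terms for lex in resources.lexicons)))
        dict_batches = _dictionary_batches(
            words, resources.lexicons, resources.inventory,
            resources.transfer_batch_size, cfg.max_len,
        )

    def p_step(ids) -> None:
        ptn.train_batch(ids)
        optimizer.step(ptn.params())
        step_log.append("P")

    def d_step(batch) -> None:
        ids, labels = batch
        dtn.train_batch(ids, labels)
        optimizer.step(dtn.params())
        step_log.append("D")

    # --- pre-main blocks ---------------------------------------------------
    if spec.dictionary == "before_predictive":
        for b in dict_batches:
            d_step(b)
        for b in pred_batches:
            p_step(b)
    elif spec.dictionary == "after_predictive":
        for b in pred_batches:
            p_step(b)
        for b in dict_batches:
            d_step(b)
    elif spec.dictionary == "interleaved_with_predictive":
        pi, di = iter(pred_batches), iter(dict_batches)
        while True:
            done = True
            b = next(pi, None)
            if b is not None:
                p_step(b)
                done = False
            b = next(di, None)
            if b is not None:
                d_step(b)
                done = False
            if done:
                break
    else:
        if spec.predictive == "at_start":
            for b in pred_batches:
                p_step(b)
        if spec.dictionary == "at_start":
            for b in dict_batches:
                d_step(b)

    # --- interleaved-with-main phases -------------------------------------
    pred_iter: Iterator = iter(pred_batches) if spec.predictive == "interleaved" else iter(())
    dict_iter: Iterator = (
        iter(dict_batches) if spec.dictionary == "interleaved" else iter(())
    )

    def interleave(log) -> None:
        b = next(pred_iter, None)
        if b is not None:
            p_step(b)
        b = next(dict_iter, None)
        if b is not None:
            d_step(b)

    needs_interleave = spec.predictive == "interleaved" or spec.dictionary == "interleaved"
    result = tagger.fit_network(
        network,
        resources.train_docs,
        resources.heldout_docs,
        resources.entities,
        interleave=interleave if needs_interleave else None,
        step_log=step_log,
        optimizer=optimizer,
    )
    return tagger, result, step_log
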