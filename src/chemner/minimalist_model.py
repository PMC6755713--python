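"""The character-level "minimalist" tagger.

No tokeniser and no engineered features: the input is the raw character
sequence, encoded against a fixed 90-character inventory plus an unknown
character (91 indices in total), embedded by a learned lookup and fed to

* a forward LSTM (128 units) and a reversed LSTM (128 units) over the same
  characters, concatenated (256 wide) with dropout 0.5,
* two stacked bidirectional LSTMs, 64 units per direction, dropout 0.5,
* a per-character dense 5-way softmax over the SOBIE tags.

Because labelling is per character, decoded entities may start or end in
the middle of what a tokeniser would call one token — the main structural
advantage over the token-level system.  Trained for 30 epochs with a
4-epoch shortest-first length curriculum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import AnnotatedEntity, Document
from .decoder import (
    DEFAULT_THRESHOLD,
    TagProbMatrix,
    extract_entities,
    remove_overlaps,
)
from .nn import BiLSTM, Dropout, Embedding, LSTM, TimeDense, softmax_xent
from .tokenizer import SOBIE_TAGS
from .traditional_model import sobie_onehot
from .training import TaggedSequence, TrainResult, predict_sequences, train_tagger

__all__ = [
    "CharInventory",
    "DEFAULT_INVENTORY_CHARS",
    "MinimalistConfig",
    "MinimalistNetwork",
    "build_minimalist_network",
    "encode_chars",
    "char_sobie_tags",
    "MinimalistTagger",
]

# 90 known characters: letters, digits, space, common punctuation/symbols.
DEFAULT_INVENTORY_CHARS: str = (
    "abcdefghijklmnopqrstuvwxyz"
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    "0123456789"
    " .,;:!?'\"()[]{}-–/%+=<>#&*_^"
)
assert len(DEFAULT_INVENTORY_CHARS) == 90


@dataclass(frozen=True)
class CharInventory:
    """Ordered character inventory; every character maps somewhere (unknown
    characters to the last index)."""

    chars: str = DEFAULT_INVENTORY_CHARS

    def __post_init__(self) -> None:
        if len(set(self.chars)) != len(self.chars):
            raise ValueError("inventory characters must be unique")

    @property
    def size(self) -> int:
        """Total index count including the unknown index."""
        return len(self.chars) + 1

    @property
    def unknown_index(self) -> int:
        return len(self.chars)

    def encode(self, text: str) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.chars)}
        return np.array(
            [index.get(c, self.unknown_index) for c in text], dtype=np.int64
        )

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(list(self.chars), fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "CharInventory":
        with open(path, encoding="utf-8") as fh:
            return cls("".join(json.load(fh)))


def encode_chars(text: str, inventory: CharInventory | None = None) -> np.ndarray:
    """Length-preserving integer encoding; unknown characters map to the
    91st index."""
    return (inventory or CharInventory()).encode(text)


def char_sobie_tags(text: str, entities: Sequence[AnnotatedEntity]) -> list[str]:
    """Per-character SOBIE tags (a 1-character entity is S)."""
    tags = ["O"] * len(text)
    for e in sorted(entities, key=lambda e: e.start):
        if e.end > len(text):
            raise ValueError(f"entity [{e.start}, {e.end}) beyond text length")
        if e.end - e.start == 1:
            tags[e.start] = "S"
        else:
            tags[e.start] = "B"
            for k in range(e.start + 1, e.end - 1):
                tags[k] = "I"
            tags[e.end - 1] = "E"
    return tags


@dataclass
class MinimalistConfig:
    """Hyperparameters of the character tagger."""

    char_embed_dim: int = 64
    lstm_units: int = 128  # ml1 forward / ml2 reversed
    concat_dropout: float = 0.5
    bilstm_units: int = 64  # per direction, mb1 and mb2
    bilstm_dropout: float = 0.5
    recurrent_dropout: bool = False
    epochs: int = 30
    curriculum_epochs: int = 4
    batch_size: int = 32
    learning_rate: float = 1e-3
    max_len: int = 2000  # longer inputs are chunked at whitespace
    seed: int = 42


class MinimalistNetwork:
    """Single-input character network; see module docstring for the layout."""

    def __init__(
        self,
        config: MinimalistConfig,
        inventory: CharInventory | None = None,
        dtype=np.float32,
    ) -> None:
        self.config = config
        self.inventory = inventory or CharInventory()
        rng = np.random.default_rng(config.seed)
        u, bu = config.lstm_units, config.bilstm_units
        rdrop = 0.5 if config.recurrent_dropout else 0.0
        self.embed = Embedding(
            self.inventory.size, config.char_embed_dim, rng, dtype=dtype
        )
        self.ml1 = LSTM(config.char_embed_dim, u, rng, reverse=False, dtype=dtype)
        self.ml2 = LSTM(config.char_embed_dim, u, rng, reverse=True, dtype=dtype)
        self.mm1_drop = Dropout(config.concat_dropout)
        self.mb1 = BiLSTM(
            2 * u, bu, rng, dropout=config.bilstm_dropout,
            recurrent_dropout=rdrop, dtype=dtype,
        )
        self.mb2 = BiLSTM(
            2 * bu, bu, rng, dropout=config.bilstm_dropout,
            recurrent_dropout=rdrop, dtype=dtype,
        )
        self.md1 = TimeDense(
            2 * bu, len(SOBIE_TAGS), rng, activation="softmax", dtype=dtype
        )
        self._rng = rng

    def params(self):
        return (
            self.embed.params() + self.ml1.params() + self.ml2.params()
            + self.mb1.params() + self.mb2.params() + self.md1.params()
        )

    def forward(self, ids: np.ndarray, train: bool = False) -> np.ndarray:
        x = self.embed.forward(ids, train)
        h1 = self.ml1.forward(x, train, self._rng)
        h2 = self.ml2.forward(x, train, self._rng)
        m = np.concatenate([h1, h2], axis=2)
        m = self.mm1_drop.forward(m, train, self._rng)
        b1 = self.mb1.forward(m, train, self._rng)
        b2 = self.mb2.forward(b1, train, self._rng)
        return self.md1.forward(b2, train)

    def train_batch(self, xs: tuple[np.ndarray], y: np.ndarray) -> float:
        (ids,) = xs
        probs = self.forward(ids, train=True)
        loss, dz = softmax_xent(probs, y)
        d = self.md1.backward(dz)
        d = self.mb2.backward(d)
        d = self.mb1.backward(d)
        d = self.mm1_drop.backward(d)
        u = self.config.lstm_units
        dx = self.ml1.backward(d[:, :, :u]) + self.ml2.backward(d[:, :, u:])
        self.embed.backward(dx)
        return loss

    def predict_probs_batch(self, xs: tuple[np.ndarray]) -> np.ndarray:
        (ids,) = xs
        return self.forward(ids, train=False)

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.value[...] = w


def build_minimalist_network(
    config: MinimalistConfig, inventory: CharInventory | None = None
) -> MinimalistNetwork:
    return MinimalistNetwork(config, inventory)


def _chunk_spans(text: str, max_len: int) -> list[tuple[int, int]]:
    """Split [0, len) into chunks of at most max_len, at whitespace where
    possible."""
    spans = []
    start = 0
    n = len(text)
    while n - start > max_len:
        cut = text.rfind(" ", start + 1, start + max_len)
        if cut <= start:
            cut = start + max_len
        spans.append((start, cut))
        start = cut
    if n > start:
        spans.append((start, n))
    return spans


class MinimalistTagger:
    """End-to-end character-level pipeline."""

    def __init__(
        self,
        config: MinimalistConfig | None = None,
        inventory: CharInventory | None = None,
    ) -> None:
        self.config = config or MinimalistConfig()
        self.inventory = inventory or CharInventory()
        self.network: MinimalistNetwork | None = None
        self.result: TrainResult | None = None

    def build_sequences(
        self,
        documents: Sequence[Document],
        entities: Sequence[AnnotatedEntity] = (),
        with_targets: bool = True,
    ) -> list[TaggedSequence]:
        by_df: dict[tuple[str, str], list[AnnotatedEntity]] = {}
        for e in entities:
            by_df.setdefault((e.doc_id, e.field), []).append(e)
        seqs = []
        for doc in documents:
            for field in ("T", "A"):
                text = doc.field_text(field)
                if not text:
                    continue
                ents = by_df.get((doc.doc_id, field), [])
                for cs, ce in _chunk_spans(text, self.config.max_len):
                    chunk = text[cs:ce]
                    chunk_ents = [e for e in ents if cs <= e.start and e.end <= ce]
                    if with_targets:
                        local = [
                            AnnotatedEntity(
                                e.doc_id, e.field, e.start - cs, e.end - cs,
                                e.text, e.score,
                            )
                            for e in chunk_ents
                        ]
                        onehot = sobie_onehot(char_sobie_tags(chunk, local))
                    else:
                        onehot = None
                    seqs.append(
                        TaggedSequence(
                            inputs=(self.inventory.encode(chunk),),
                            onehot=onehot,
                            doc_id=doc.doc_id,
                            field=field,
                            text=text,
                            offsets=[(cs + i, cs + i + 1) for i in range(len(chunk))],
                            gold=list(chunk_ents),
                        )
                    )
        return seqs

    def fit(
        self,
        train_docs: Sequence[Document],
        heldout_docs: Sequence[Document],
        entities: Sequence[AnnotatedEntity],
        log_path=None,
        interleave=None,
        step_log=None,
        optimizer=None,
    ) -> TrainResult:
        cfg = self.config
        self.network = MinimalistNetwork(cfg, self.inventory)
        return self.fit_network(
            self.network, train_docs, heldout_docs, entities,
            log_path=log_path, interleave=interleave, step_log=step_log,
            optimizer=optimizer,
        )

    def fit_network(
        self,
        network: MinimalistNetwork,
        train_docs: Sequence[Document],
        heldout_docs: Sequence[Document],
        entities: Sequence[AnnotatedEntity],
        log_path=None,
        interleave=None,
        step_log=None,
        optimizer=None,
    ) -> TrainResult:
        """Train a pre-built network (used by transfer schedules, which
        pre-train shared layers before main training)."""
        cfg = self.config
        self.network = network
        train_seqs = self.build_sequences(train_docs, entities, with_targets=True)
        heldout_seqs = self.build_sequences(heldout_docs, entities, with_targets=True)
        self.result = train_tagger(
            network,
            train_seqs,
            heldout_seqs,
            epochs=cfg.epochs,
            curriculum_epochs=cfg.curriculum_epochs,
            batch_size=cfg.batch_size,
            lr=cfg.learning_rate,
            seed=cfg.seed,
            log_path=log_path,
            interleave=interleave,
            step_log=step_log,
            optimizer=optimizer,
        )
        return self.result

    def predict_char_probs(self, documents: Sequence[Document]) -> list[TagProbMatrix]:
        if self.network is None:
            raise RuntimeError("tagger is not fitted")
        seqs = self.build_sequences(documents, (), with_targets=False)
        mats = predict_sequences(self.network, seqs)
        # concatenate chunk matrices of the same (doc, field)
        groups: dict[tuple[str, str], list[TagProbMatrix]] = {}
        order: list[tuple[str, str]] = []
        for m in mats:
            key = (m.doc_id, m.field)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(m)
        out = []
        for key in order:
            group = groups[key]
            if len(group) == 1:
                out.append(group[0])
            else:
                out.append(
                    TagProbMatrix(
                        np.concatenate([g.probs for g in group]),
                        [o for g in group for o in g.offsets],
                        key[0], key[1], group[0].text,
                    )
                )
        return out

    def predict(
        self,
        documents: Sequence[Document],
        threshold: float = DEFAULT_THRESHOLD,
        resolve_overlaps: bool = True,
    ) -> list[AnnotatedEntity]:
        ents: list[AnnotatedEntity] = []
        for m in self.predict_char_probs(documents):
            ents.extend(extract_entities(m, threshold))
        return remove_overlaps(ents) if resolve_overlaps else ents

    # -- persistence -------------------------------------------------------

    def save(self, outdir: str | Path) -> None:
        """Write the model bundle: weights, inventory, config, format tag."""
        import dataclasses

        if self.network is None:
            raise RuntimeError("tagger is not fitted")
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        weights = self.network.get_weights()
        np.savez(outdir / "weights.npz", **{f"w{i}": w for i, w in enumerate(weights)})
        self.inventory.to_json(outdir / "inventory.json")
        with open(outdir / "config.json", "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self.config), fh, indent=1)
        with open(outdir / "format.json", "w", encoding="utf-8") as fh:
            json.dump({"format": "chemner-minimalist", "version": 1}, fh)

    @classmethod
    def load(cls, outdir: str | Path) -> "MinimalistTagger":
        outdir = Path(outdir)
        with open(outdir / "format.json", encoding="utf-8") as fh:
            fmt = json.load(fh)
        if fmt.get("format") != "chemner-minimalist":
            raise ValueError(f"not a minimalist model bundle: {outdir}")
        with open(outdir / "config.json", encoding="utf-8") as fh:
            config = MinimalistConfig(**json.load(fh))
        inventory = CharInventory.from_json(outdir / "inventory.json")
        tagger = cls(config, inventory)
        tagger.network = MinimalistNetwork(config, inventory)
        data = np.load(outdir / "weights.npz")
        tagger.network.set_weights([data[f"w{i}"] for i in range(len(data.files))])
        return tagger
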