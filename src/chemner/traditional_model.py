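"""The token-level "traditional" tagger.

Architecture (per-token, over whole title/abstract fields):

* input 1: token indices -> trainable embedding (default 300-wide,
  GloVe-initialised where coverage exists, zeros elsewhere);
* input 2: engineered per-token feature vectors -> width-3 convolution over
  the token axis, 256 relu filters, dropout 0.5;
* the two are concatenated (556 wide at the defaults) and fed to a
  bidirectional LSTM with 64 units per direction (dropout 0.5, optional
  recurrent dropout), then a per-token dense 5-way softmax over the SOBIE
  tags.

Trained with RMSProp on categorical cross-entropy, mini-batches of
equal-length sequences, best-of-20-epochs selection by held-out strict F.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .corpus_io import AnnotatedEntity, Document
from .decoder import (
    DEFAULT_THRESHOLD,
    TagProbMatrix,
    extract_entities,
    remove_overlaps,
)
from .embeddings import Vocabulary, build_vocab, init_embedding_matrix
from .featurizer import (
    DEFAULT_REGEXES,
    Lexicon,
    TokenFeaturizer,
    top_common_features,
    train_preclassifier,
)
from .nn import BiLSTM, Conv1DSame, Dropout, Embedding, TimeDense, softmax_xent
from .tokenizer import (
    SOBIE_TAGS,
    assign_sobie,
    split_tokens_at_boundaries,
    tokenize,
)
from .training import TaggedSequence, TrainResult, train_tagger

__all__ = [
    "TraditionalConfig",
    "TraditionalNetwork",
    "build_traditional_network",
    "TraditionalTagger",
    "train_tagger",
    "TagProbMatrix",
    "sobie_onehot",
    "split_train_heldout",
]

_TAG_INDEX = {t: i for i, t in enumerate(SOBIE_TAGS)}


@dataclass
class TraditionalConfig:
    """Hyperparameters of the token tagger (defaults are the distributed
    system's values)."""

    embed_dim: int = 300
    conv_filters: int = 256
    conv_width: int = 3
    conv_dropout: float = 0.5
    lstm_units_per_direction: int = 64
    lstm_dropout: float = 0.5
    recurrent_dropout: bool = False  # 0.5 when enabled (slower, CPU-era setup)
    epochs: int = 20
    batch_size: int = 32
    learning_rate: float = 1e-3
    min_count: int = 2
    seed: int = 42

    def __post_init__(self) -> None:
        for name in ("conv_dropout", "lstm_dropout"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")


def sobie_onehot(tags: Sequence[str]) -> np.ndarray:
    """(T, 5) one-hot targets in (S, O, B, I, E) column order."""
    y = np.zeros((len(tags), len(SOBIE_TAGS)), dtype=np.float32)
    for i, t in enumerate(tags):
        y[i, _TAG_INDEX[t]] = 1.0
    return y


class TraditionalNetwork:
    """The two-input token network; see module docstring for the layout."""

    def __init__(
        self,
        config: TraditionalConfig,
        vocab_size: int,
        feature_dim: int,
        embedding_init: np.ndarray | None = None,
        dtype=np.float32,
    ) -> None:
        if embedding_init is not None and embedding_init.shape[1] != config.embed_dim:
            raise ValueError(
                f"embedding init dim {embedding_init.shape[1]} != "
                f"config embed_dim {config.embed_dim}"
            )
        self.config = config
        self.feature_dim = feature_dim
        rng = np.random.default_rng(config.seed)
        if embedding_init is None:
            embedding_init = np.zeros((vocab_size, config.embed_dim), dtype=dtype)
        self.te1 = Embedding(
            vocab_size, config.embed_dim, rng, init=embedding_init, dtype=dtype
        )
        self.tc1 = Conv1DSame(
            feature_dim, config.conv_filters, config.conv_width, rng, dtype=dtype
        )
        self.tc1_drop = Dropout(config.conv_dropout)
        self.concat_width = config.embed_dim + config.conv_filters
        rdrop = 0.5 if config.recurrent_dropout else 0.0
        self.tb1 = BiLSTM(
            self.concat_width,
            config.lstm_units_per_direction,
            rng,
            dropout=config.lstm_dropout,
            recurrent_dropout=rdrop,
            dtype=dtype,
        )
        self.td1 = TimeDense(
            2 * config.lstm_units_per_direction, len(SOBIE_TAGS), rng,
            activation="softmax", dtype=dtype,
        )
        self._rng = rng

    def params(self):
        return (
            self.te1.params() + self.tc1.params() + self.tb1.params()
            + self.td1.params()
        )

    def forward(self, ids: np.ndarray, feats: np.ndarray, train: bool = False):
        e = self.te1.forward(ids, train)
        c = self.tc1.forward(feats, train)
        c = self.tc1_drop.forward(c, train, self._rng)
        m = np.concatenate([e, c], axis=2)
        h = self.tb1.forward(m, train, self._rng)
        return self.td1.forward(h, train)

    def train_batch(self, xs: tuple[np.ndarray, np.ndarray], y: np.ndarray) -> float:
        ids, feats = xs
        probs = self.forward(ids, feats, train=True)
        loss, dz = softmax_xent(probs, y)
        dh = self.td1.backward(dz)
        dm = self.tb1.backward(dh)
        de = dm[:, :, : self.config.embed_dim]
        dc = dm[:, :, self.config.embed_dim :]
        dc = self.tc1_drop.backward(dc)
        self.tc1.backward(dc)
        self.te1.backward(de)
        return loss

    def predict_probs_batch(self, xs: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
        ids, feats = xs
        return self.forward(ids, feats, train=False)

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.value[...] = w


def build_traditional_network(
    config: TraditionalConfig,
    vocab_size: int,
    feature_dim: int,
    embedding_init: np.ndarray | None = None,
) -> TraditionalNetwork:
    return TraditionalNetwork(config, vocab_size, feature_dim, embedding_init)


def split_train_heldout(
    documents: Sequence[Document], fraction: float = 0.8, seed: int = 42
) -> tuple[list[Document], list[Document]]:
    """Deterministic 80:20 document split for training vs model selection."""
    idx = np.random.default_rng(seed).permutation(len(documents))
    cut = int(round(fraction * len(documents)))
    train = [documents[i] for i in idx[:cut]]
    heldout = [documents[i] for i in idx[cut:]]
    return train, heldout


def _entities_by_doc_field(
    entities: Sequence[AnnotatedEntity],
) -> dict[tuple[str, str], list[AnnotatedEntity]]:
    out: dict[tuple[str, str], list[AnnotatedEntity]] = {}
    for e in entities:
        out.setdefault((e.doc_id, e.field), []).append(e)
    return out


class TraditionalTagger:
    """End-to-end pipeline: tokenise, featurize, train, decode.

    ``fit`` expects a pre-split train/heldout document partition (the usual
    80:20); gold boundary splitting of tokens is applied to the training
    side only.
    """

    def __init__(
        self,
        config: TraditionalConfig,
        lexicons: Sequence[Lexicon],
        regexes=DEFAULT_REGEXES,
    ) -> None:
        self.config = config
        self.lexicons = tuple(lexicons)
        self.regexes = tuple(regexes)
        self.vocab: Vocabulary | None = None
        self.featurizer: TokenFeaturizer | None = None
        self.network: TraditionalNetwork | None = None
        self.result: TrainResult | None = None

    # -- sequence building -------------------------------------------------

    def _train_sequences(
        self,
        documents: Sequence[Document],
        entities: Sequence[AnnotatedEntity],
    ) -> tuple[list[tuple[Document, str, list, list[str]]], list[list[str]]]:
        """Tokenised training fields with boundary splitting and SOBIE tags."""
        by_df = _entities_by_doc_field(entities)
        fields = []
        token_lists = []
        for doc in documents:
            for field in ("T", "A"):
                text = doc.field_text(field)
                if not text:
                    continue
                ents = by_df.get((doc.doc_id, field), [])
                toks = split_tokens_at_boundaries(tokenize(text), ents)
                if not toks:
                    continue
                tags = assign_sobie(toks, ents)
                fields.append((doc, field, toks, tags, ents))
                token_lists.append([t.text for t in toks])
        return fields, token_lists

    def fit(
        self,
        train_docs: Sequence[Document],
        heldout_docs: Sequence[Document],
        entities: Sequence[AnnotatedEntity],
        pretrained_embeddings: dict[str, np.ndarray] | None = None,
        log_path=None,
    ) -> TrainResult:
        cfg = self.config
        fields, token_lists = self._train_sequences(train_docs, entities)
        if not fields:
            raise ValueError("no non-empty training fields")

        self.vocab = build_vocab(token_lists, min_count=cfg.min_count)

        # preclassifier on unambiguous token types
        type_tags: dict[str, set[str]] = {}
        for _, _, toks, tags, _ in fields:
            for tok, tag in zip(toks, tags):
                type_tags.setdefault(tok.text, set()).add(
                    "O" if tag == "O" else "SBIE"
                )
        token_types = [
            (text, 0 if tags == {"O"} else 1)
            for text, tags in sorted(type_tags.items())
            if len(tags) == 1
        ]
        bundle = train_preclassifier(
            token_types, self.lexicons, self.regexes, seed=cfg.seed
        )
        all_tokens = [t for toks in token_lists for t in toks]
        self.featurizer = TokenFeaturizer(bundle, top_common_features(all_tokens))

        if pretrained_embeddings:
            table = init_embedding_matrix(self.vocab, pretrained_embeddings)
            if table.dimension != cfg.embed_dim:
                cfg.embed_dim = table.dimension
            emb_init = table.rows
        else:
            emb_init = None
        self.network = TraditionalNetwork(
            cfg, len(self.vocab), self.featurizer.dim, emb_init
        )

        train_seqs = [
            self._sequence(doc, field, toks, tags, ents)
            for doc, field, toks, tags, ents in fields
        ]
        heldout_seqs = self._inference_sequences(heldout_docs, entities)
        self.result = train_tagger(
            self.network,
            train_seqs,
            heldout_seqs,
            epochs=cfg.epochs,
            curriculum_epochs=0,
            batch_size=cfg.batch_size,
            lr=cfg.learning_rate,
            seed=cfg.seed,
            log_path=log_path,
        )
        return self.result

    def _sequence(self, doc, field, toks, tags, ents) -> TaggedSequence:
        texts = [t.text for t in toks]
        return TaggedSequence(
            inputs=(
                self.vocab.encode(texts),
                self.featurizer.matrix(texts),
            ),
            onehot=sobie_onehot(tags) if tags is not None else None,
            doc_id=doc.doc_id,
            field=field,
            text=doc.field_text(field),
            offsets=[(t.start, t.end) for t in toks],
            gold=list(ents),
        )

    def _inference_sequences(
        self,
        documents: Sequence[Document],
        entities: Sequence[AnnotatedEntity] = (),
    ) -> list[TaggedSequence]:
        by_df = _entities_by_doc_field(entities)
        seqs = []
        for doc in documents:
            for field in ("T", "A"):
                text = doc.field_text(field)
                if not text:
                    continue
                toks = tokenize(text)
                if not toks:
                    continue
                ents = by_df.get((doc.doc_id, field), [])
                tags = ["O"] * len(toks)  # placeholder targets, unused
                seqs.append(self._sequence(doc, field, toks, tags, ents))
        return seqs

    # -- inference ---------------------------------------------------------

    def predict_token_probs(self, documents: Sequence[Document]) -> list[TagProbMatrix]:
        from .training import predict_sequences

        if self.network is None:
            raise RuntimeError("tagger is not fitted")
        return predict_sequences(self.network, self._inference_sequences(documents))

    def predict(
        self,
        documents: Sequence[Document],
        threshold: float = DEFAULT_THRESHOLD,
        resolve_overlaps: bool = True,
    ) -> list[AnnotatedEntity]:
        ents: list[AnnotatedEntity] = []
        for m in self.predict_token_probs(documents):
            ents.extend(extract_entities(m, threshold))
        return remove_overlaps(ents) if resolve_overlaps else ents

    # -- persistence -------------------------------------------------------

    def save(self, outdir) -> None:
        """Write the model bundle: weights, vocab, preclassifier, feature
        lists, config snapshot, format tag."""
        import dataclasses
        import json
        from pathlib import Path

        import joblib

        if self.network is None:
            raise RuntimeError("tagger is not fitted")
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        weights = self.network.get_weights()
        np.savez(outdir / "weights.npz", **{f"w{i}": w for i, w in enumerate(weights)})
        with open(outdir / "vocab.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "index": self.vocab.index,
                    "unknown_index": self.vocab.unknown_index,
                    "min_count": self.vocab.min_count,
                },
                fh,
            )
        joblib.dump(self.featurizer.bundle, outdir / "preclassifier.joblib")
        with open(outdir / "top100.json", "w", encoding="utf-8") as fh:
            json.dump(self.featurizer.top100, fh)
        with open(outdir / "config.json", "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self.config), fh, indent=1)
        with open(outdir / "format.json", "w", encoding="utf-8") as fh:
            json.dump({"format": "chemner-traditional", "version": 1}, fh)

    @classmethod
    def load(cls, outdir) -> "TraditionalTagger":
        import json
        from pathlib import Path

        import joblib

        outdir = Path(outdir)
        with open(outdir / "format.json", encoding="utf-8") as fh:
            fmt = json.load(fh)
        if fmt.get("format") != "chemner-traditional":
            raise ValueError(f"not a traditional model bundle: {outdir}")
        with open(outdir / "config.json", encoding="utf-8") as fh:
            config = TraditionalConfig(**json.load(fh))
        bundle = joblib.load(outdir / "preclassifier.joblib")
        with open(outdir / "top100.json", encoding="utf-8") as fh:
            top100 = json.load(fh)
        tagger = cls(config, bundle.lexicons, bundle.regexes)
        tagger.featurizer = TokenFeaturizer(bundle, top100)
        with open(outdir / "vocab.json", encoding="utf-8") as fh:
            v = json.load(fh)
        tagger.vocab = Vocabulary(v["index"], v["unknown_index"], v["min_count"])
        tagger.network = TraditionalNetwork(
            config, len(tagger.vocab), tagger.featurizer.dim
        )
        data = np.load(outdir / "weights.npz")
        tagger.network.set_weights([data[f"w{i}"] for i in range(len(data.files))])
        return tagger
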