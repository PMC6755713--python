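"""Deterministic generator of toy annotated corpora with chemistry-like
entities.

The generator emits every artifact the pipeline consumes — a document file,
gold annotations with exact offsets, lexicon files, a plain-text transfer
corpus and a small embedding file — so the whole system is testable without
downloads.  Chemical-like names follow a small morpheme grammar
(stem(+stem)*suffix, optional multiplier, e.g. "dichlorethane") or a
formula branch ("C6H12O6"-style), and are distinguishable from the filler
vocabulary by suffix statistics, so small models can learn them quickly.
Realism beyond that is a non-goal.

A few filler words are also planted in the chemical lexicon, and a few
names occasionally appear unannotated in filler slots, so that the
preclassifier's handling of ambiguous token types is exercised.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus_io import AnnotatedEntity, Document

__all__ = [
    "GeneratorParams",
    "SyntheticCorpus",
    "generate_chemical_name",
    "generate_annotated_corpus",
    "generate_corpus",
]

_STEMS = (
    "meth", "eth", "prop", "but", "pent", "hex", "benz", "chlor", "fluor",
    "brom", "nitr", "sulf", "phen", "acet", "oxal", "glyc",
)
_MULTIPLIERS = ("di", "tri", "tetra")
_SUFFIXES = (
    "ane", "ene", "ol", "yl", "ate", "ide", "ine", "one", "amine", "oxide",
)
_ELEMENT_SYMBOLS = (
    "C", "H", "O", "N", "S", "P", "Na", "Cl", "K", "Ca", "Fe", "Mg", "Br", "Zn",
)
_ELEMENT_NAMES = (
    "carbon", "hydrogen", "oxygen", "nitrogen", "sulfur", "phosphorus",
    "sodium", "chlorine", "potassium", "calcium", "iron", "magnesium",
    "bromine", "zinc",
)
_FILLERS = (
    "the", "a", "was", "were", "added", "slowly", "mixture", "solution",
    "sample", "reaction", "with", "under", "stirring", "heated", "cooled",
    "room", "temperature", "yield", "product", "obtained", "after", "hours",
    "filtered", "dried", "washed", "water", "residue", "solvent", "excess",
    "then", "resulting", "crude", "pure", "white", "solid", "pale", "layer",
    "aqueous", "organic", "combined", "reduced", "pressure", "overnight",
    "ambient", "conditions", "typical", "procedure", "analysis", "improved",
    "process",
)
# Filler words also planted in the chemical lexicon (ambiguity injection).
_AMBIGUOUS_FILLERS = ("lead", "salt")


@dataclass(frozen=True)
class GeneratorParams:
    """Conditions of the synthetic study; the seed fully determines output."""

    n_documents: int = 100
    entity_rate: float = 1.5  # mean entities per abstract sentence
    sentences_per_abstract: int = 1
    title_entity_prob: float = 0.3
    formula_prob: float = 0.2  # formula branch vs morpheme grammar
    ambiguous_rate: float = 0.02  # chance a filler slot takes a known name
    n_lexicon_names: int = 300
    n_transfer_lines: int = 200
    embedding_dim: int = 16
    seed: int = 0


@dataclass
class SyntheticCorpus:
    """In-memory corpus plus the auxiliary artifacts, with file writers."""

    documents: list[Document]
    entities: list[AnnotatedEntity]
    chemical_lexicon: list[str]
    element_lexicon: list[str]
    english_lexicon: list[str]
    transfer_lines: list[str]
    embeddings: dict[str, np.ndarray]

    def write_files(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "documents": outdir / "documents.tsv",
            "annotations": outdir / "annotations.tsv",
            "chemical_lexicon": outdir / "lexicon_chemicals.txt",
            "element_lexicon": outdir / "lexicon_elements.txt",
            "english_lexicon": outdir / "lexicon_english.txt",
            "transfer": outdir / "transfer.txt",
            "embeddings": outdir / "embeddings.txt",
        }
        with open(paths["documents"], "w", encoding="utf-8") as fh:
            for d in self.documents:
                fh.write(f"{d.doc_id}\t{d.title}\t{d.abstract}\n")
        with open(paths["annotations"], "w", encoding="utf-8") as fh:
            for e in self.entities:
                fh.write(
                    f"{e.doc_id}\t{e.field}\t{e.start}\t{e.end}\t{e.text}"
                    f"\t{e.score:.6f}\n"
                )
        for key, terms in (
            ("chemical_lexicon", self.chemical_lexicon),
            ("element_lexicon", self.element_lexicon),
            ("english_lexicon", self.english_lexicon),
        ):
            with open(paths[key], "w", encoding="utf-8") as fh:
                fh.write("".join(t + "\n" for t in terms))
        with open(paths["transfer"], "w", encoding="utf-8") as fh:
            fh.write("".join(line + "\n" for line in self.transfer_lines))
        with open(paths["embeddings"], "w", encoding="utf-8") as fh:
            for token, vec in self.embeddings.items():
                vals = " ".join(f"{v:.4f}" for v in vec)
                fh.write(f"{token} {vals}\n")
        return paths


def generate_chemical_name(rng: np.random.Generator, formula_prob: float = 0.2) -> str:
    """One chemical-like name: morpheme grammar or a formula-like token."""
    if rng.random() < formula_prob:
        n_parts = int(rng.integers(2, 5))
        parts = []
        for _ in range(n_parts):
            sym = _ELEMENT_SYMBOLS[int(rng.integers(len(_ELEMENT_SYMBOLS)))]
            if rng.random() < 0.6:
                sym += str(int(rng.integers(1, 13)))
            parts.append(sym)
        return "".join(parts)
    name = ""
    if rng.random() < 0.3:
        name += _MULTIPLIERS[int(rng.integers(len(_MULTIPLIERS)))]
    n_stems = 1 + int(rng.random() < 0.45)
    for _ in range(n_stems):
        name += _STEMS[int(rng.integers(len(_STEMS)))]
    name += _SUFFIXES[int(rng.integers(len(_SUFFIXES)))]
    return name


# Sentence templates by number of entity slots.  'E' marks an entity slot,
# 'F' a filler-word slot; remaining words are literal.
_TEMPLATES: dict[int, tuple[tuple[str, ...], ...]] = {
    0: (
        ("The", "F", "F", "was", "F", "at", "F", "temperature."),
        ("A", "F", "F", "was", "obtained", "after", "F", "hours."),
    ),
    1: (
        ("The", "E", "was", "added", "to", "the", "F", "mixture."),
        ("A", "F", "solution", "of", "E", "was", "F", "overnight."),
        ("Treatment", "with", "E", "gave", "a", "F", "F."),
    ),
    2: (
        ("The", "E", "was", "F", "with", "E", "under", "F", "conditions."),
        ("Addition", "of", "E", "to", "E", "gave", "a", "F", "product."),
    ),
    3: (
        ("E", "reacted", "with", "E", "to", "give", "E", "in", "F", "yield."),
    ),
}

_TITLE_TEMPLATES_E = (("Synthesis", "of", "E"), ("Preparation", "of", "E"))
_TITLE_TEMPLATES_0 = (("Improved", "F", "process"), ("A", "F", "F", "method"))


def _fill_template(
    template: Sequence[str],
    rng: np.random.Generator,
    params: GeneratorParams,
    ambiguous_pool: Sequence[str],
) -> tuple[str, list[tuple[int, int, str]]]:
    """Render a template; returns text and (start, end, text) entity spans."""
    words: list[str] = []
    spans: list[tuple[int, int, str]] = []
    pos = 0
    for slot in template:
        if words:
            pos += 1  # joining space
        if slot == "E":
            word = generate_chemical_name(rng, params.formula_prob)
            spans.append((pos, pos + len(word), word))
        elif slot == "F":
            if ambiguous_pool and rng.random() < params.ambiguous_rate:
                word = ambiguous_pool[int(rng.integers(len(ambiguous_pool)))]
            else:
                word = _FILLERS[int(rng.integers(len(_FILLERS)))]
        else:
            word = slot
        words.append(word)
        pos += len(word)
    return " ".join(words), spans


def generate_annotated_corpus(
    params: GeneratorParams,
) -> tuple[list[Document], list[AnnotatedEntity]]:
    """Generate documents and gold annotations (exact offsets)."""
    rng = np.random.default_rng(params.seed)
    # pool of names that may appear unannotated (ambiguous token types)
    ambiguous_pool = [generate_chemical_name(rng) for _ in range(3)]
    ambiguous_pool += list(_AMBIGUOUS_FILLERS)
    documents: list[Document] = []
    entities: list[AnnotatedEntity] = []
    for d in range(params.n_documents):
        doc_id = f"SYN{d:05d}"
        title_prob = params.title_entity_prob if params.entity_rate > 0 else 0.0
        if rng.random() < title_prob:
            tmpl = _TITLE_TEMPLATES_E[int(rng.integers(len(_TITLE_TEMPLATES_E)))]
        else:
            tmpl = _TITLE_TEMPLATES_0[int(rng.integers(len(_TITLE_TEMPLATES_0)))]
        title, tspans = _fill_template(tmpl, rng, params, ambiguous_pool)
        abstract_parts: list[str] = []
        aspans: list[tuple[int, int, str]] = []
        offset = 0
        for _ in range(params.sentences_per_abstract):
            if abstract_parts:
                offset += 1
            k = min(int(rng.poisson(params.entity_rate)), 3)
            choices = _TEMPLATES[k]
            sent_tmpl = choices[int(rng.integers(len(choices)))]
            text, spans = _fill_template(sent_tmpl, rng, params, ambiguous_pool)
            abstract_parts.append(text)
            aspans.extend((s + offset, e + offset, t) for s, e, t in spans)
            offset += len(text)
        abstract = " ".join(abstract_parts)
        documents.append(Document(doc_id, title, abstract))
        for s, e, t in tspans:
            entities.append(AnnotatedEntity(doc_id, "T", s, e, t, 1.0))
        for s, e, t in aspans:
            entities.append(AnnotatedEntity(doc_id, "A", s, e, t, 1.0))
    return documents, entities


def generate_corpus(
    params: GeneratorParams, outdir: str | Path | None = None
) -> SyntheticCorpus:
    """Generate the full artifact set; optionally write it to ``outdir``."""
    documents, entities = generate_annotated_corpus(params)
    rng = np.random.default_rng(params.seed + 1_000_003)

    chem_lex = sorted(
        {generate_chemical_name(rng, params.formula_prob)
         for _ in range(params.n_lexicon_names)}
    )
    chem_lex += list(_AMBIGUOUS_FILLERS)  # ambiguity injection
    english = sorted(set(_FILLERS) | set(_AMBIGUOUS_FILLERS))

    transfer_params = GeneratorParams(
        n_documents=params.n_transfer_lines,
        entity_rate=params.entity_rate,
        sentences_per_abstract=1,
        seed=params.seed + 7,
    )
    tdocs, _ = generate_annotated_corpus(transfer_params)
    transfer_lines = [d.abstract for d in tdocs]

    emb_vocab = list(_FILLERS) + list(_AMBIGUOUS_FILLERS) + chem_lex[:50]
    emb_vocab += ["The", "A", "Treatment", "Addition", "Synthesis", "Preparation"]
    embeddings = {
        w: rng.uniform(-0.5, 0.5, params.embedding_dim).astype(np.float32)
        for w in dict.fromkeys(emb_vocab)
    }

    corpus = SyntheticCorpus(
        documents=documents,
        entities=entities,
        chemical_lexicon=chem_lex,
        element_lexicon=list(_ELEMENT_NAMES),
        english_lexicon=english,
        transfer_lines=transfer_lines,
        embeddings=embeddings,
    )
    if outdir is not None:
        corpus.write_files(outdir)
    return corpus
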