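"""Chemistry-aware tokenisation and SOBIE tag assignment.

The tokeniser follows the behaviour of the Oscar4 family of chemistry
tokenisers at the level this tagger depends on: split on whitespace, detach
leading/trailing bracket/punctuation characters, keep internal hyphens,
primes and digits attached (so "2-methylpropane" stays whole), and split
around standalone reaction symbols.  The exact rule set is declared here so
behaviour is versioned and stable.

SOBIE (= BIOES) tags mark Single-token entities, the Beginning, Inside and
End of multi-token entities, and Outside tokens.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .corpus_io import AnnotatedEntity

__all__ = [
    "Token",
    "SOBIE_TAGS",
    "tokenize",
    "split_tokens_at_boundaries",
    "assign_sobie",
    "is_valid_tag_sequence",
]

#: Tag order used everywhere a 5-way probability row appears.
SOBIE_TAGS: tuple[str, ...] = ("S", "O", "B", "I", "E")

# Characters detached from token edges, one at a time.
_EDGE_PUNCT = set("()[]{},.;:!?\"'")
# Symbols split out wherever they occur inside a chunk.
_SPLIT_SYMBOLS = set("=+→")  # = + →

_WS_CHUNK = re.compile(r"\S+")


@dataclass(frozen=True)
class Token:
    """A token with its source-text span (0-based, end exclusive)."""

    text: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty token span at {self.start}")


def _split_chunk(chunk: str, offset: int) -> list[Token]:
    """Tokenise one whitespace-free chunk into edge punctuation, split
    symbols and the remaining core pieces."""
    if not chunk:
        return []
    # Peel leading edge punctuation.
    lead = 0
    while lead < len(chunk) and chunk[lead] in _EDGE_PUNCT:
        lead += 1
    trail = len(chunk)
    while trail > lead and chunk[trail - 1] in _EDGE_PUNCT:
        trail -= 1
    tokens = [Token(c, offset + i, offset + i + 1) for i, c in enumerate(chunk[:lead])]
    core = chunk[lead:trail]
    pos = lead
    if core:
        piece_start = pos
        for i, ch in enumerate(core, start=lead):
            if ch in _SPLIT_SYMBOLS:
                if i > piece_start:
                    tokens.append(
                        Token(chunk[piece_start:i], offset + piece_start, offset + i)
                    )
                tokens.append(Token(ch, offset + i, offset + i + 1))
                piece_start = i + 1
        if trail > piece_start:
            tokens.append(
                Token(chunk[piece_start:trail], offset + piece_start, offset + trail)
            )
    tokens.extend(
        Token(c, offset + trail + i, offset + trail + i + 1)
        for i, c in enumerate(chunk[trail:])
    )
    return tokens


def tokenize(text: str) -> list[Token]:
    """Tokenise ``text``; token texts always equal their source slices."""
    tokens: list[Token] = []
    for m in _WS_CHUNK.finditer(text):
        tokens.extend(_split_chunk(m.group(), m.start()))
    return tokens


def split_tokens_at_boundaries(
    tokens: Sequence[Token], entities: Sequence[AnnotatedEntity]
) -> list[Token]:
    """Split tokens so every entity boundary coincides with a token edge.

    Used on training data only: the tagger is never allowed to "see" gold
    boundaries at inference time.
    """
    cuts: set[int] = set()
    for e in entities:
        cuts.add(e.start)
        cuts.add(e.end)
    out: list[Token] = []
    for tok in tokens:
        inner = sorted(c for c in cuts if tok.start < c < tok.end)
        if not inner:
            out.append(tok)
            continue
        edges = [tok.start, *inner, tok.end]
        for a, b in zip(edges, edges[1:]):
            out.append(Token(tok.text[a - tok.start : b - tok.start], a, b))
    return out


def assign_sobie(
    tokens: Sequence[Token], entities: Sequence[AnnotatedEntity]
) -> list[str]:
    """Assign one SOBIE tag per token.

    Entity boundaries must align with token boundaries (run
    :func:`split_tokens_at_boundaries` first on training data) and entities
    must not overlap.
    """
    tags = ["O"] * len(tokens)
    start_index = {t.start: i for i, t in enumerate(tokens)}
    end_index = {t.end: i for i, t in enumerate(tokens)}
    for e in sorted(entities, key=lambda e: e.start):
        if e.start not in start_index or e.end not in end_index:
            raise ValueError(
                f"entity span [{e.start}, {e.end}) {e.text!r} does not align "
                "with token boundaries"
            )
        i, j = start_index[e.start], end_index[e.end]
        if any(t != "O" for t in tags[i : j + 1]):
            raise ValueError(
                f"overlapping entity span [{e.start}, {e.end}) {e.text!r}"
            )
        if i == j:
            tags[i] = "S"
        else:
            tags[i] = "B"
            for k in range(i + 1, j):
                tags[k] = "I"
            tags[j] = "E"
    return tags


def is_valid_tag_sequence(tags: Sequence[str]) -> bool:
    """True iff every B is followed by E with only I between, and I/E never
    follow O or S directly."""
    in_entity = False
    for t in tags:
        if t not in SOBIE_TAGS:
            return False
        if in_entity:
            if t not in ("I", "E"):
                return False
            if t == "E":
                in_entity = False
        else:
            if t in ("I", "E"):
                return False
            if t == "B":
                in_entity = True
    return not in_entity
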