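"""Token-level feature engineering and the random-forest preclassifier.

The token tagger is fed, per token, a "chemicalness" probability from a
preclassifier plus two direct feature sets:

* three character-class counts (non-lowercase, non-letter, digit) and one
  binary bit per lexicon and per regular expression;
* presence bits for the 100 most common features among 2-/3-character
  suffixes and word shapes.

The preclassifier is a 100-tree random forest over the 1000 binary features
(word shapes, boundary-marked character 1-4-grams, regex and lexicon tests)
with the highest mutual information against the O-only vs SBIE-only token
type labels.  Token *types* (not instances) are the sampling unit, and types
ever tagged both ways are excluded.  Scores for the training types come from
a 5-fold cross-scoring scheme so no type is scored by a forest that saw it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold

__all__ = [
    "Lexicon",
    "DEFAULT_REGEXES",
    "word_shape",
    "char_ngrams",
    "surface_features",
    "select_by_mutual_information",
    "train_preclassifier",
    "PreclassifierBundle",
    "top_common_features",
    "token_feature_vector",
    "TokenFeaturizer",
]


@dataclass(frozen=True)
class Lexicon:
    """A named term list with exact, case-sensitive membership by default."""

    name: str
    terms: frozenset[str]
    case_sensitive: bool = True

    @classmethod
    def from_file(cls, name: str, path: str | Path, case_sensitive: bool = True) -> "Lexicon":
        with open(path, encoding="utf-8") as fh:
            terms = frozenset(line.strip() for line in fh if line.strip())
        return cls(name, terms, case_sensitive)

    def __contains__(self, term: str) -> bool:
        if self.case_sensitive:
            return term in self.terms
        return term.lower() in {t.lower() for t in self.terms}


#: Default full-token regular expression tests.  The originals used by
#: chemistry NER systems vary; this set is representative and configurable.
DEFAULT_REGEXES: tuple[tuple[str, str], ...] = (
    ("chemical_formula", r"([A-Z][a-z]?\d*)+"),
    ("contains_digit", r".*\d.*"),
    ("all_caps", r"[A-Z]+"),
    ("internal_hyphen", r".+-.+"),
    ("chemical_suffix", r".*(yl|ol|ane|ene|ate|ide|ine|one)"),
    ("cas_number", r"\d{2,7}-\d{2}-\d"),
)


def _compiled(regexes: Sequence[tuple[str, str]]) -> list[tuple[str, re.Pattern]]:
    return [(name, re.compile(pat)) for name, pat in regexes]


def word_shape(token_text: str) -> str:
    """Collapse a token to its shape: ``A`` for uppercase, ``a`` for
    lowercase, ``0`` for digits, other characters kept; maximal runs of the
    same symbol collapse to one.

    >>> word_shape("2,4-dinitrophenol")
    '0,0-a'
    """
    if not token_text:
        raise ValueError("word_shape of empty string")
    out: list[str] = []
    for ch in token_text:
        if ch.isupper():
            sym = "A"
        elif ch.islower():
            sym = "a"
        elif ch.isdigit():
            sym = "0"
        else:
            sym = ch
        if not out or out[-1] != sym:
            out.append(sym)
    return "".join(out)


def char_ngrams(token_text: str, n: int) -> set[str]:
    """Character n-grams of ``^token$`` (boundary markers give prefixes and
    suffixes); set semantics."""
    if n < 1:
        raise ValueError("n must be >= 1")
    marked = "^" + token_text + "$"
    return {marked[i : i + n] for i in range(max(len(marked) - n + 1, 1))}


def surface_features(
    token_text: str,
    lexicons: Sequence[Lexicon],
    regexes: Sequence[tuple[str, str]] = DEFAULT_REGEXES,
) -> tuple[tuple[int, int, int], np.ndarray]:
    """Character-class counts plus one bit per lexicon and per regex.

    Counts are (non-lowercase, non-letter, digit).  Regex bits are
    full-token matches.
    """
    non_lower = sum(1 for c in token_text if not c.islower())
    non_letter = sum(1 for c in token_text if not c.isalpha())
    digits = sum(1 for c in token_text if c.isdigit())
    bits = np.zeros(len(lexicons) + len(regexes), dtype=np.float32)
    for i, lex in enumerate(lexicons):
        if token_text in lex:
            bits[i] = 1.0
    for j, (_, pat) in enumerate(_compiled(regexes)):
        if pat.fullmatch(token_text):
            bits[len(lexicons) + j] = 1.0
    return (non_lower, non_letter, digits), bits


def select_by_mutual_information(
    feature_presence: np.ndarray, labels: np.ndarray, k: int
) -> list[int]:
    """Rank binary features by mutual information with a binary label.

    MI is the plug-in (maximum-likelihood) estimate from the 2x2 contingency
    counts; ties break by feature id.  If ``k`` exceeds the feature count all
    features are returned (a warning is emitted).
    """
    X = np.asarray(feature_presence, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    n, n_feat = X.shape
    if k > n_feat:
        import warnings

        warnings.warn(
            f"requested {k} features but only {n_feat} available; returning all"
        )
        k = n_feat
    n11 = X.T @ y
    n10 = X.sum(axis=0) - n11
    n01 = y.sum() - n11
    n00 = n - n11 - n10 - n01
    counts = np.stack([n00, n01, n10, n11], axis=1)  # (n_feat, 4)
    p = counts / n
    px1 = (n10 + n11) / n
    py1 = y.sum() / n
    marg = np.stack(
        [
            (1 - px1) * (1 - py1),
            (1 - px1) * py1,
            px1 * (1 - py1),
            px1 * py1,
        ],
        axis=1,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / marg)
    terms[~np.isfinite(terms)] = 0.0
    mi = terms.sum(axis=1)
    order = np.lexsort((np.arange(n_feat), -mi))
    return [int(i) for i in order[:k]]


def _binary_feature_names(token_text: str, lexicons, regexes) -> set[str]:
    feats = {"shape=" + word_shape(token_text)}
    for n in (1, 2, 3, 4):
        feats.update(f"{n}g={g}" for g in char_ngrams(token_text, n))
    for lex in lexicons:
        if token_text in lex:
            feats.add("lex=" + lex.name)
    for name, pat in _compiled(regexes):
        if pat.fullmatch(token_text):
            feats.add("re=" + name)
    return feats


@dataclass
class PreclassifierBundle:
    """A trained preclassifier: the main forest over the selected features,
    plus held-out-fold scores for every training token type."""

    feature_ids: dict[str, int]  # selected feature name -> column
    forest: RandomForestClassifier
    cross_scores: dict[str, float]  # training token type -> held-out score
    fold_of_type: dict[str, int]
    lexicons: tuple[Lexicon, ...]
    regexes: tuple[tuple[str, str], ...]

    def _vector(self, token_text: str) -> np.ndarray:
        v = np.zeros(len(self.feature_ids), dtype=np.float32)
        for name in _binary_feature_names(token_text, self.lexicons, self.regexes):
            col = self.feature_ids.get(name)
            if col is not None:
                v[col] = 1.0
        return v

    def score(self, token_text: str) -> float:
        """Chemicalness probability: the cross-score for known training
        types, the main forest for unseen tokens."""
        if token_text in self.cross_scores:
            return self.cross_scores[token_text]
        proba = self.forest.predict_proba(self._vector(token_text)[None, :])[0]
        # column for class 1 (SBIE); guard the degenerate single-class case
        classes = list(self.forest.classes_)
        return float(proba[classes.index(1)]) if 1 in classes else 0.0


def train_preclassifier(
    token_types: Sequence[tuple[str, int]],
    lexicons: Sequence[Lexicon],
    regexes: Sequence[tuple[str, str]] = DEFAULT_REGEXES,
    n_features: int = 1000,
    n_trees: int = 100,
    n_folds: int = 5,
    seed: int = 42,
) -> PreclassifierBundle:
    """Train the preclassifier on unambiguous token types.

    ``token_types`` pairs each distinct token string with label 0 (only ever
    tagged O) or 1 (only ever tagged S/B/I/E).  Returns the main forest plus
    a held-out score per training type from the 5-fold cross-scoring models.
    """
    if len(token_types) < 10:
        raise ValueError("need at least 10 distinct token types")
    labels = np.array([lab for _, lab in token_types])
    if len(set(labels.tolist())) < 2:
        raise ValueError("preclassifier needs both O-only and SBIE-only types")

    lexicons = tuple(lexicons)
    regexes = tuple(regexes)
    per_type = [
        _binary_feature_names(text, lexicons, regexes) for text, _ in token_types
    ]
    all_names = sorted(set().union(*per_type))
    col = {name: i for i, name in enumerate(all_names)}
    X_all = np.zeros((len(token_types), len(all_names)), dtype=np.float32)
    for row, feats in enumerate(per_type):
        for name in feats:
            X_all[row, col[name]] = 1.0

    selected = select_by_mutual_information(X_all, labels, n_features)
    feature_ids = {all_names[j]: i for i, j in enumerate(selected)}
    X = X_all[:, selected]

    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X, labels)

    cross_scores: dict[str, float] = {}
    fold_of_type: dict[str, int] = {}
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for fold, (train_idx, test_idx) in enumerate(kf.split(X)):
        sub = RandomForestClassifier(n_estimators=n_trees, random_state=seed + 1 + fold)
        sub.fit(X[train_idx], labels[train_idx])
        classes = list(sub.classes_)
        proba = sub.predict_proba(X[test_idx])
        scores = proba[:, classes.index(1)] if 1 in classes else np.zeros(len(test_idx))
        for i, s in zip(test_idx, scores):
            text = token_types[i][0]
            cross_scores[text] = float(s)
            fold_of_type[text] = fold
    return PreclassifierBundle(
        feature_ids, forest, cross_scores, fold_of_type, lexicons, regexes
    )


def top_common_features(token_texts: Sequence[str], k: int = 100) -> list[str]:
    """The ``k`` most common features among 2-/3-character suffixes and word
    shapes over the given tokens (instances); ties break lexicographically."""
    from collections import Counter

    counts: Counter[str] = Counter()
    for text in token_texts:
        marked = text + "$"
        feats = {"shape=" + word_shape(text)}
        if len(marked) >= 2:
            feats.add("suf2=" + marked[-2:])
        if len(marked) >= 3:
            feats.add("suf3=" + marked[-3:])
        counts.update(feats)
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in ranked[:k]]


def token_feature_vector(
    token_text: str,
    bundle: PreclassifierBundle,
    top100: Sequence[str],
) -> np.ndarray:
    """Assemble the per-token feature vector fed to the network:
    [preclassifier score, 3 counts, lexicon/regex bits, top-100 bits]."""
    (nl, nal, dg), bits = surface_features(token_text, bundle.lexicons, bundle.regexes)
    marked = token_text + "$"
    own = {"shape=" + word_shape(token_text)}
    if len(marked) >= 2:
        own.add("suf2=" + marked[-2:])
    if len(marked) >= 3:
        own.add("suf3=" + marked[-3:])
    top_bits = np.array([1.0 if f in own else 0.0 for f in top100], dtype=np.float32)
    head = np.array([bundle.score(token_text), nl, nal, dg], dtype=np.float32)
    return np.concatenate([head, bits, top_bits])


@dataclass
class TokenFeaturizer:
    """Bundles everything needed to featurize tokens consistently."""

    bundle: PreclassifierBundle
    top100: list[str]

    @property
    def dim(self) -> int:
        return 4 + len(self.bundle.lexicons) + len(self.bundle.regexes) + len(self.top100)

    def matrix(self, token_texts: Sequence[str]) -> np.ndarray:
        if not token_texts:
            return np.zeros((0, self.dim), dtype=np.float32)
        return np.stack(
            [token_feature_vector(t, self.bundle, self.top100) for t in token_texts]
        ).astype(np.float32)
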