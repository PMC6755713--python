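"""Feature extraction, mutual-information selection, preclassifier."""

import math

import numpy as np
import pytest

from chemner.featurizer import (
    Lexicon,
    TokenFeaturizer,
    char_ngrams,
    select_by_mutual_information,
    surface_features,
    token_feature_vector,
    top_common_features,
    train_preclassifier,
    word_shape,
)


class TestWordShape:
    @pytest.mark.parametrize(
        "token,shape",
        [
            ("NaCl", "AaAa"),
            ("2,4-dinitrophenol", "0,0-a"),
            ("water", "a"),
            ("ABC123", "A0"),
            ("pH", "aA"),
        ],
    )
    def test_examples(self, token, shape):
        assert word_shape(token) == shape

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            word_shape("")


class TestCharNgrams:
    def test_trigram_boundaries(self):
        assert char_ngrams("ol", 3) == {"^ol", "ol$"}

    def test_unigrams(self):
        assert char_ngrams("a", 1) == {"^", "a", "$"}

    def test_fourgram_suffix_prefix(self):
        grams = char_ngrams("ether", 4)
        assert "ther" in grams and "her$" in grams and "^eth" in grams


class TestSurfaceFeatures:
    def test_counts_nacl(self):
        counts, _ = surface_features("NaCl", [])
        assert counts == (2, 0, 0)

    def test_counts_24d(self):
        # per definition: 5 non-lowercase, 4 non-letter, 2 digits
        counts, _ = surface_features("2,4-D", [])
        assert counts == (5, 4, 2)

    def test_lexicon_and_regex_bits(self):
        eng = Lexicon("english", frozenset({"water"}))
        counts, bits = surface_features("water", [eng])
        assert counts == (0, 0, 0)
        assert bits[0] == 1.0  # lexicon membership
        _, bits2 = surface_features("NaCl2", [eng])
        assert bits2[0] == 0.0
        assert bits2[1] == 1.0  # chemical_formula regex
        assert bits2[2] == 1.0  # contains_digit


def mi_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Direct-summation MI over the 2x2 table (independent of the
    vectorised implementation)."""
    n = len(x)
    total = 0.0
    for a in (0, 1):
        for b in (0, 1):
            p_ab = sum(1 for i in range(n) if x[i] == a and y[i] == b) / n
            p_a = sum(1 for i in range(n) if x[i] == a) / n
            p_b = sum(1 for i in range(n) if y[i] == b) / n
            if p_ab > 0 and p_a > 0 and p_b > 0:
                total += p_ab * math.log(p_ab / (p_a * p_b))
    return total


class TestMISelection:
    def test_label_copy_ranked_first_constant_last(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        X = np.column_stack([np.ones(6), y, [0, 1, 1, 0, 1, 0]])
        order = select_by_mutual_information(X, y, 3)
        assert order[0] == 1  # identical to label
        assert order[-1] == 0  # constant, MI = 0

    def test_toy_table_matches_oracle(self):
        rng = np.random.default_rng(3)
        X = (rng.random((6, 3)) < 0.5).astype(float)
        y = np.array([0, 0, 0, 1, 1, 1])
        order = select_by_mutual_information(X, y, 3)
        scores = [mi_oracle(X[:, j], y) for j in range(3)]
        expected = sorted(range(3), key=lambda j: (-scores[j], j))
        assert order == expected

    def test_k_too_large_warns_and_returns_all(self):
        X = np.eye(4)
        y = np.array([0, 1, 0, 1])
        with pytest.warns(UserWarning):
            assert len(select_by_mutual_information(X, y, 10)) == 4


@pytest.fixture(scope="module")
def trained_bundle():
    chem = Lexicon("chemical", frozenset({"acetone", "benzene", "ethanol"}))
    eng = Lexicon("english", frozenset({"water", "the", "sample"}))
    types = [
        ("acetone", 1), ("benzene", 1), ("ethanol", 1), ("methanol", 1),
        ("propanol", 1), ("butanol", 1), ("chloride", 1), ("sulfate", 1),
        ("the", 0), ("water", 0), ("sample", 0), ("was", 0), ("added", 0),
        ("slowly", 0), ("mixture", 0), ("heated", 0),
    ]
    return types, train_preclassifier(types, [chem, eng], seed=1)


class TestPreclassifier:
    def test_every_type_scored_by_excluding_fold(self, trained_bundle):
        types, bundle = trained_bundle
        assert set(bundle.cross_scores) == {t for t, _ in types}
        # fold bookkeeping: each type assigned exactly one fold, 5 folds used
        assert set(bundle.fold_of_type.values()) <= {0, 1, 2, 3, 4}

    def test_unseen_token_scored_in_range(self, trained_bundle):
        _, bundle = trained_bundle
        s = bundle.score("pyrazinamide")
        assert 0.0 <= s <= 1.0

    def test_deterministic_given_seed(self, trained_bundle):
        types, bundle = trained_bundle
        again = train_preclassifier(
            types, list(bundle.lexicons), bundle.regexes, seed=1
        )
        assert again.cross_scores == bundle.cross_scores
        assert again.score("pyrazinamide") == bundle.score("pyrazinamide")

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_preclassifier([(f"w{i}", 0) for i in range(12)], [])

    def test_too_few_types_rejected(self):
        with pytest.raises(ValueError):
            train_preclassifier([("a", 0), ("b", 1)], [])


class TestFeatureVector:
    def test_suffix_bit_and_constant_length(self, trained_bundle):
        types, bundle = trained_bundle
        top = top_common_features([t for t, _ in types], k=10)
        fz = TokenFeaturizer(bundle, top)
        toks = ["chloride", "water", "XQ#7"]
        mat = fz.matrix(toks)
        assert mat.shape == (3, fz.dim)
        v = token_feature_vector("chloride", bundle, top)
        if "suf3=de$" in top:
            assert v[4 + len(bundle.lexicons) + len(bundle.regexes) + top.index("suf3=de$")] == 1.0

    def test_no_matching_top_feature_gives_zero_bits(self, trained_bundle):
        _, bundle = trained_bundle
        v = token_feature_vector("zzz", bundle, ["suf3=ide", "shape=A0"])
        assert v[-2:].tolist() == [0.0, 0.0]

    def test_extraction_pure(self, trained_bundle):
        _, bundle = trained_bundle
        top = ["suf2=e$", "shape=a"]
        a = token_feature_vector("acetone", bundle, top)
        b = token_feature_vector("acetone", bundle, top)
        assert np.array_equal(a, b)
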