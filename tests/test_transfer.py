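"""Transfer-learning heads, weight sharing and schedule execution."""

import numpy as np
import pytest

from chemner.featurizer import Lexicon
from chemner.minimalist_model import MinimalistConfig, MinimalistNetwork
from chemner.nn import GlobalMaxPool, RMSProp
from chemner.transfer import (
    DictionaryTransferNetwork,
    PredictiveTransferNetwork,
    ScheduleResources,
    ScheduleSpec,
    VALID_SCHEDULES,
    run_training_schedule,
    shift_targets,
    train_predictive,
    word_membership_labels,
)
from chemner.synthetic import GeneratorParams, generate_corpus


class TestShiftTargets:
    def test_definition(self):
        left, right = shift_targets(np.array([5, 7, 9]), n_classes=12)
        assert left[0, 7] == 1 and left[1, 9] == 1
        assert left[2].sum() == 0  # padding row
        assert right[0].sum() == 0
        assert right[1, 5] == 1 and right[2, 7] == 1

    def test_round_trip_recovers_shifted_input(self):
        ids = np.array([3, 1, 4, 1, 5])
        left, _ = shift_targets(ids, n_classes=8)
        decoded = left[:-1].argmax(axis=1)
        assert np.array_equal(decoded, ids[1:])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            shift_targets(np.array([1]))

    def test_constant_sequence(self):
        left, right = shift_targets(np.array([2, 2, 2]), n_classes=5)
        assert np.array_equal(left[:2].argmax(axis=1), [2, 2])
        assert np.array_equal(right[1:].argmax(axis=1), [2, 2])


@pytest.fixture()
def small_cfg():
    return MinimalistConfig(
        char_embed_dim=8, lstm_units=12, bilstm_units=6,
        epochs=1, curriculum_epochs=0, batch_size=4, seed=3,
    )


class TestWeightSharing:
    def test_predictive_heads_share_main_layers(self, small_cfg):
        main = MinimalistNetwork(small_cfg)
        ptn = PredictiveTransferNetwork(main)
        assert ptn.ml1 is main.ml1 and ptn.ml2 is main.ml2
        assert ptn.embed is main.embed

    def test_transfer_step_updates_main_parameters(self, small_cfg):
        main = MinimalistNetwork(small_cfg)
        ptn = PredictiveTransferNetwork(main)
        before = main.ml1.Wx.value.copy()
        opt = RMSProp()
        ids = np.tile(np.arange(10), (2, 1))
        ptn.train_batch(ids)
        opt.step(ptn.params())
        assert not np.array_equal(before, main.ml1.Wx.value)

    def test_predictive_heads_are_91way_softmax(self):
        main = MinimalistNetwork(MinimalistConfig(seed=1))
        ptn = PredictiveTransferNetwork(main)
        ids = np.arange(15)[None, :]
        p_left, p_right = ptn.forward(ids)
        assert p_left.shape == (1, 15, 91) and p_right.shape == (1, 15, 91)
        assert np.allclose(p_left.sum(axis=2), 1.0, atol=1e-5)
        assert np.allclose(p_right.sum(axis=2), 1.0, atol=1e-5)

    def test_dictionary_head_shares_full_stack(self, small_cfg):
        main = MinimalistNetwork(small_cfg)
        dtn = DictionaryTransferNetwork(main)
        before = main.mb2.fw.Wx.value.copy()
        ids = np.tile(np.arange(6), (2, 1))
        labels = np.array([[1, 0, 0], [0, 1, 1]], dtype=np.float32)
        dtn.train_batch(ids, labels)
        RMSProp().step(dtn.params())
        assert not np.array_equal(before, main.mb2.fw.Wx.value)
        out = dtn.forward(ids)
        assert out.shape == (2, 3)
        assert ((out >= 0) & (out <= 1)).all()


def test_max_pool_invariant_under_repetition():
    pool = GlobalMaxPool()
    x = np.random.default_rng(0).standard_normal((2, 5, 7))
    once = pool.forward(x)
    twice = pool.forward(np.concatenate([x, x], axis=1))
    assert np.allclose(once, twice)


class TestMembershipLabels:
    def test_examples(self):
        chem = Lexicon("chemical", frozenset({"benzene"}))
        elem = Lexicon("element", frozenset({"sodium"}))
        eng = Lexicon("english", frozenset({"sodium", "water"}))
        lex = [chem, elem, eng]
        assert word_membership_labels("sodium", lex).tolist() == [0, 1, 1]
        assert word_membership_labels("quartz", lex).tolist() == [0, 0, 0]
        chem2 = Lexicon("chemical", frozenset({"sodium"}))
        assert word_membership_labels("sodium", [chem2, elem, eng]).tolist() == [1, 1, 1]

    def test_wrong_lexicon_count_rejected(self):
        with pytest.raises(ValueError):
            word_membership_labels("x", [])


class TestScheduleSpec:
    def test_eleven_valid_combinations(self):
        assert len(VALID_SCHEDULES) == 11

    def test_invalid_combination_rejected_with_listing(self):
        with pytest.raises(ValueError, match="valid combinations"):
            ScheduleSpec("at_start", "at_start")


@pytest.fixture(scope="module")
def schedule_resources():
    corpus = generate_corpus(GeneratorParams(
        n_documents=16, n_transfer_lines=10, seed=4,
    ))
    cfg = MinimalistConfig(
        char_embed_dim=8, lstm_units=12, bilstm_units=6,
        epochs=1, curriculum_epochs=0, batch_size=8, seed=3,
    )
    lexicons = (
        Lexicon("chemical", frozenset(corpus.chemical_lexicon[:12])),
        Lexicon("element", frozenset(corpus.element_lexicon[:6])),
        Lexicon("english", frozenset(corpus.english_lexicon[:12])),
    )
    return ScheduleResources(
        config=cfg,
        train_docs=corpus.documents[:12],
        heldout_docs=corpus.documents[12:],
        entities=corpus.entities,
        transfer_lines=corpus.transfer_lines,
        lexicons=lexicons,
        transfer_batch_size=8,
    )


class TestSchedules:
    def test_no_transfer_log_is_main_only(self, schedule_resources):
        _, _, log = run_training_schedule(ScheduleSpec("none", "none"),
                                          schedule_resources)
        assert set(log) == {"M"} and len(log) > 0

    def test_predictive_at_start_block_precedes_main(self, schedule_resources):
        _, _, log = run_training_schedule(ScheduleSpec("at_start", "none"),
                                          schedule_resources)
        assert "P" in log and "M" in log
        assert log.index("M") > max(i for i, s in enumerate(log) if s == "P")

    def test_dictionary_interleaving_stops_when_words_exhausted(
        self, schedule_resources
    ):
        from chemner.transfer import _dictionary_batches

        n_batches = len(_dictionary_batches(
            sorted(set().union(*(l.terms for l in schedule_resources.lexicons))),
            schedule_resources.lexicons,
            schedule_resources.inventory,
            schedule_resources.transfer_batch_size,
            schedule_resources.config.max_len,
        ))
        _, _, log = run_training_schedule(ScheduleSpec("none", "interleaved"),
                                          schedule_resources)
        assert log.count("D") == n_batches

    def test_schedule_reproducible_given_seed(self, schedule_resources):
        _, r1, log1 = run_training_schedule(
            ScheduleSpec("interleaved", "none"), schedule_resources
        )
        _, r2, log2 = run_training_schedule(
            ScheduleSpec("interleaved", "none"), schedule_resources
        )
        assert log1 == log2
        assert [h["loss"] for h in r1.history] == [h["loss"] for h in r2.history]
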