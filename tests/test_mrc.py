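"""Tests for the question-conditioned span extraction pipeline."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy.special import logsumexp as scipy_logsumexp

from mrispan.corpus_io import DWI_HIGH, OTHER_PART, ReportDocument
from mrispan.encoder import CLS_ID, SEP_ID, EncoderConfig, build_vocab
from mrispan.mrc import (DEFAULT_QUESTION, GoldPositionLabels, IndicatorSequence,
                         LossValue, MrcInput, PositionProbabilities,
                         QuestionTooLongError, SpanPair, build_mrc_input,
                         indicators, load_mrc, match_spans, mrc_loss,
                         position_probabilities, predict_corpus, predict_spans,
                         save_mrc, spans_to_gold_labels, train_mrc)
from mrispan.synthetic import CorpusConfig, generate_corpus
from mrispan.training import TrainingConfig

from conftest import make_doc


# independent decoding oracles live in tests/oracles.py

from oracles import enumerate_pairings, exhaustive_greedy_oracle, \
    recursive_greedy_oracle


class TestMatchSpans:
    def test_worked_example(self):
        i_start = [0, 1, 0, 0, 0, 0, 1, 0, 0, 0]
        i_end = [0, 0, 0, 1, 0, 0, 0, 0, 0, 1]
        assert match_spans(i_start, i_end) == [SpanPair(2, 4), SpanPair(7, 10)]

    def test_all_zero(self):
        assert match_spans([0] * 6, [0] * 6) == []

    def test_leading_end_discarded(self):
        # starts {3}, ends {1, 5} -> the end at 1 precedes every start
        got = match_spans([0, 0, 1, 0, 0], [1, 0, 0, 0, 1])
        assert got == [SpanPair(3, 5)]
        assert exhaustive_greedy_oracle([0, 0, 1, 0, 0], [1, 0, 0, 0, 1]) \
            == [(3, 5)]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            match_spans([0, 1], [0, 1, 0])

    def test_exhaustive_oracle_up_to_length_six(self):
        for n in range(1, 7):
            for s_bits in itertools.product([0, 1], repeat=n):
                for e_bits in itertools.product([0, 1], repeat=n):
                    got = [(p.start, p.end) for p in match_spans(s_bits, e_bits)]
                    assert got == exhaustive_greedy_oracle(s_bits, e_bits), \
                        (s_bits, e_bits)

    def test_indicator_sequence_inputs(self):
        s = IndicatorSequence(np.array([0, 1, 0]), "start")
        e = IndicatorSequence(np.array([0, 0, 1]), "end")
        assert match_spans(s, e) == [SpanPair(2, 3)]

    def test_pairs_non_overlapping_random(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 30))
            s = rng.integers(0, 2, size=n)
            e = rng.integers(0, 2, size=n)
            pairs = match_spans(s, e)
            for a, b in zip(pairs, pairs[1:]):
                assert a.end < b.start


class TestPositionProbabilities:
    def test_zero_head_gives_uniform_rows(self):
        E = np.ones((5, 8))
        P = position_probabilities(E, np.zeros((8, 2)))
        np.testing.assert_allclose(P.values, 0.5)

    def test_rows_sum_to_one_and_match_logsumexp_reference(self, rng):
        for _ in range(20):
            E = rng.normal(size=(9, 6)) * 5
            T = rng.normal(size=(6, 2)) * 5
            P = position_probabilities(E, T)
            np.testing.assert_allclose(P.values.sum(axis=1), 1.0, atol=1e-9)
            logits = E @ T
            ref = np.exp(logits - scipy_logsumexp(logits, axis=1, keepdims=True))
            np.testing.assert_allclose(P.values, ref, atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            position_probabilities(np.ones((3, 4)), np.ones((5, 2)))

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            PositionProbabilities(np.array([[0.9, 0.3]]), "start")


class TestIndicators:
    def test_row_07_is_not_boundary(self):
        P = PositionProbabilities(np.array([[0.3, 0.7]]), "start")
        assert indicators(P).values.tolist() == [0]

    def test_row_08_is_boundary(self):
        P = PositionProbabilities(np.array([[0.8, 0.2]]), "start")
        assert indicators(P).values.tolist() == [1]

    def test_exact_tie_breaks_negative(self):
        P = PositionProbabilities(np.array([[0.5, 0.5]]), "end")
        assert indicators(P).values.tolist() == [0]


class TestGoldLabels:
    def test_no_positive_spans(self):
        doc = make_doc("abcdef", [(0, 3, OTHER_PART)])
        labels = spans_to_gold_labels(doc)
        assert labels.y_start.sum() == 0 and labels.y_end.sum() == 0

    def test_single_span_positions(self):
        # span over characters 2-4 in 1-based inclusive speech = [1, 4)
        doc = make_doc("abcdef", [(1, 4, DWI_HIGH)])
        labels = spans_to_gold_labels(doc)
        assert labels.y_start.tolist() == [0, 1, 0, 0, 0, 0]
        assert labels.y_end.tolist() == [0, 0, 0, 1, 0, 0]

    def test_label_decoder_consistency_on_synthetic_docs(self):
        corpus = generate_corpus(CorpusConfig(n_reports=200, seed=17))
        for doc in corpus:
            labels = spans_to_gold_labels(doc)
            pairs = match_spans(labels.y_start, labels.y_end)
            decoded = [(p.start - 1, p.end) for p in pairs]
            gold = [(a.start, a.end) for a in doc.annotations
                    if a.label == DWI_HIGH]
            assert decoded == gold, doc.doc_id

    def test_truncation_drops_overhanging_span(self):
        doc = make_doc("abcdef", [(4, 6, DWI_HIGH)])
        labels = spans_to_gold_labels(doc, n=5)
        assert labels.y_start.sum() == 0


class TestMrcLoss:
    def test_perfect_prediction_zero_loss(self):
        P = PositionProbabilities(np.array([[1.0, 0.0], [0.0, 1.0]]), "start")
        labels = GoldPositionLabels(np.array([1, 0]), np.array([1, 0]))
        loss = mrc_loss(P, P, labels)
        assert loss.total == pytest.approx(0.0, abs=1e-9)

    def test_uniform_rows_ln2(self):
        P = PositionProbabilities(np.full((2, 2), 0.5), "start")
        labels = GoldPositionLabels(np.array([1, 0]), np.array([0, 0]))
        loss = mrc_loss(P, P, labels)
        assert loss.l_start == pytest.approx(np.log(2))
        assert loss.l_end == pytest.approx(np.log(2))
        assert loss.total == loss.l_start + loss.l_end

    def test_matches_direct_formula_oracle(self, rng):
        probs_s = rng.dirichlet([1, 1], size=5)
        probs_e = rng.dirichlet([1, 1], size=5)
        y_s = rng.integers(0, 2, 5)
        y_e = rng.integers(0, 2, 5)
        loss = mrc_loss(PositionProbabilities(probs_s, "start"),
                        PositionProbabilities(probs_e, "end"),
                        GoldPositionLabels(y_s, y_e))
        ref_s = -np.mean([np.log(probs_s[i, 0] if y_s[i] else probs_s[i, 1])
                          for i in range(5)])
        ref_e = -np.mean([np.log(probs_e[i, 0] if y_e[i] else probs_e[i, 1])
                          for i in range(5)])
        assert loss.l_start == pytest.approx(ref_s)
        assert loss.l_end == pytest.approx(ref_e)

    def test_positive_when_imperfect(self):
        P = PositionProbabilities(np.array([[0.9, 0.1]]), "start")
        labels = GoldPositionLabels(np.array([1]), np.array([1]))
        assert mrc_loss(P, P, labels).total > 0


class TestBuildInput:
    def test_layout_arithmetic(self, small_corpus):
        vocab = build_vocab(small_corpus, extra_texts=["abc"])
        report = ReportDocument("d", "hello"[:5])
        inp = build_mrc_input("abc", report, vocab, max_length=50)
        assert len(inp.tokens) == 10
        assert inp.report_offset == 5
        assert inp.tokens[0] == CLS_ID
        assert inp.tokens[4] == SEP_ID

    def test_default_question(self):
        assert DEFAULT_QUESTION == "找出报告中dwi高信号部位"

    def test_truncation_arithmetic(self):
        text = "x" * 500
        doc = ReportDocument("d", text,
                             [type("A", (), {})] and [])
        doc = make_doc(text, [(390, 395, DWI_HIGH)])
        vocab = build_vocab([doc], extra_texts=["q" * 10])
        inp = build_mrc_input("q" * 10, doc, vocab, max_length=400)
        assert inp.n == 388
        assert len(inp.tokens) == 400
        labels = spans_to_gold_labels(doc, n=inp.n)
        assert labels.y_start.sum() == 0  # annotation past cut dropped

    def test_question_too_long(self):
        doc = make_doc("abc", [])
        vocab = build_vocab([doc], extra_texts=["q"])
        with pytest.raises(QuestionTooLongError):
            build_mrc_input("q" * 50, doc, vocab, max_length=20)

    def test_empty_question_rejected(self):
        doc = make_doc("abc", [])
        vocab = build_vocab([doc])
        with pytest.raises(ValueError):
            build_mrc_input("", doc, vocab)


# ---------------------------------------------------------------------------
# training behaviour (small, seeded)
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def memorized_model():
    doc = make_doc("naoqiao,jizhijiandwigaoxinhao.xinhaojunyun.",
                   [(0, 7, DWI_HIGH), (8, 13, DWI_HIGH)])
    config = EncoderConfig(hidden_dim=32, n_layers=1, n_heads=2,
                           max_length=80, dropout=0.0, seed=0)
    tc = TrainingConfig(learning_rate=5e-3, batch_size=1, epochs=50, seed=0)
    model = train_mrc([doc], encoder_config=config, training_config=tc)
    return model, doc


class TestTraining:
    def test_defaults_follow_published_settings(self):
        tc = TrainingConfig()
        assert tc.learning_rate == pytest.approx(3e-5)
        assert tc.batch_size == 32
        assert tc.epochs == 5
        assert tc.optimizer == "adam"

    def test_one_document_overfit(self, memorized_model):
        model, doc = memorized_model
        preds = predict_spans(model, doc)
        assert [(a.start, a.end) for a in preds] == \
            [(a.start, a.end) for a in doc.annotations]

    def test_loss_decreases(self, memorized_model):
        model, _ = memorized_model
        assert model.history[-1] < model.history[0]

    def test_seeded_repeatability(self, tiny_corpus, small_encoder_config,
                                  quick_training_config):
        a = train_mrc(tiny_corpus, encoder_config=small_encoder_config,
                      training_config=quick_training_config)
        b = train_mrc(tiny_corpus, encoder_config=small_encoder_config,
                      training_config=quick_training_config)
        assert a.history == b.history

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_mrc([])


class TestPrediction:
    def test_empty_report(self, memorized_model):
        model, _ = memorized_model
        assert predict_spans(model, ReportDocument("e", "")) == []

    def test_composition_oracle(self, memorized_model):
        # predict_spans must equal the five stages composed by hand
        from mrispan.mrc import (build_mrc_input, indicators, match_spans)
        from mrispan.encoder import encode_sequence
        model, doc = memorized_model
        inp = build_mrc_input(model.question, doc, model.vocab,
                              model.encoder_config.max_length)
        E = encode_sequence(inp.tokens, model.encoder, inp.report_offset, inp.n)
        ps = position_probabilities(E, model.t_start.data, "start")
        pe = position_probabilities(E, model.t_end.data, "end")
        pairs = match_spans(indicators(ps), indicators(pe))
        manual = [(p.start - 1, p.end) for p in pairs]
        auto = [(a.start, a.end) for a in predict_spans(model, doc)]
        assert manual == auto

    def test_checkpoint_round_trip(self, memorized_model, tmp_path):
        model, doc = memorized_model
        save_mrc(model, tmp_path / "ckpt")
        back = load_mrc(tmp_path / "ckpt")
        assert back.question == model.question
        a = predict_spans(model, doc)
        b = predict_spans(back, doc)
        assert a == b
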