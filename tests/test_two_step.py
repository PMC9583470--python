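"""Tests for the CRF tagger and the mention-typing stage."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mrispan.corpus_io import DWI_HIGH, OTHER_PART, PART, TagSequence
from mrispan.encoder import EncoderConfig, build_vocab
from mrispan.synthetic import CorpusConfig, generate_corpus
from mrispan.training import PRESETS, TrainingConfig
from mrispan.two_step import (CrfParams, MentionContext, NerTagger, NER_TAGS,
                              TypePrediction, _crf_nll_batch, bioes_legality_bias,
                              classify_mention, crf_log_partition, crf_nll,
                              crf_score, crf_viterbi, extract_mentions,
                              load_two_step, make_context, save_two_step,
                              train_fet, train_ner, two_step_predict,
                              two_step_predict_corpus)
from mrispan import nn

from conftest import make_doc


def random_crf(rng, n, T):
    emissions = rng.normal(size=(n, T)) * 2
    params = CrfParams(rng.normal(size=(T, T)), rng.normal(size=T),
                       rng.normal(size=T), tuple(f"t{i}" for i in range(T)))
    return emissions, params


def enumerate_scores(emissions, params):
    n, T = emissions.shape
    return {path: crf_score(emissions, params, list(path))
            for path in itertools.product(range(T), repeat=n)}


class TestCrfScore:
    def test_single_position_zero_transitions(self):
        params = CrfParams(np.zeros((3, 3)), np.zeros(3), np.zeros(3),
                           ("a", "b", "c"))
        emissions = np.array([[1.0, 2.0, 3.0]])
        assert crf_score(emissions, params, [2]) == pytest.approx(3.0)

    def test_all_zeros_gives_zero_for_every_path(self):
        params = CrfParams(np.zeros((2, 2)), np.zeros(2), np.zeros(2), ("a", "b"))
        emissions = np.zeros((4, 2))
        for path in itertools.product(range(2), repeat=4):
            assert crf_score(emissions, params, list(path)) == 0.0

    def test_random_case_term_by_term(self, rng):
        emissions, params = random_crf(rng, 4, 3)
        path = [2, 0, 1, 1]
        manual = (params.start[2] + emissions[0, 2]
                  + params.transitions[2, 0] + emissions[1, 0]
                  + params.transitions[0, 1] + emissions[2, 1]
                  + params.transitions[1, 1] + emissions[3, 1]
                  + params.end[1])
        assert crf_score(emissions, params, path) == pytest.approx(manual)

    def test_path_length_mismatch(self, rng):
        emissions, params = random_crf(rng, 3, 2)
        with pytest.raises(ValueError):
            crf_score(emissions, params, [0, 1])


class TestCrfViterbi:
    def test_dominant_emissions_zero_transitions(self, rng):
        T = 4
        params = CrfParams(np.zeros((T, T)), np.zeros(T), np.zeros(T),
                           tuple("abcd"))
        emissions = rng.normal(size=(6, T))
        assert crf_viterbi(emissions, params) == \
            emissions.argmax(axis=1).tolist()

    def test_single_position(self, rng):
        emissions, params = random_crf(rng, 1, 5)
        best = crf_viterbi(emissions, params)
        scores = enumerate_scores(emissions, params)
        assert crf_score(emissions, params, best) == pytest.approx(max(scores.values()))

    def test_agrees_with_enumeration(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 7))
            T = int(rng.integers(2, 6))
            emissions, params = random_crf(rng, n, T)
            best = crf_viterbi(emissions, params)
            scores = enumerate_scores(emissions, params)
            assert crf_score(emissions, params, best) == \
                pytest.approx(max(scores.values()))

    def test_tie_breaks_to_lower_index(self):
        params = CrfParams(np.zeros((3, 3)), np.zeros(3), np.zeros(3), ("a", "b", "c"))
        emissions = np.zeros((2, 3))
        assert crf_viterbi(emissions, params) == [0, 0]


class TestCrfNll:
    def test_uniform_single_position(self):
        T = 4
        params = CrfParams(np.zeros((T, T)), np.zeros(T), np.zeros(T),
                           tuple("abcd"))
        emissions = np.zeros((1, T))
        assert crf_nll(emissions, params, [0]) == pytest.approx(np.log(T))

    def test_dominating_gold_path_nll_near_zero(self):
        T = 3
        params = CrfParams(np.zeros((T, T)), np.zeros(T), np.zeros(T), ("a", "b", "c"))
        emissions = np.full((4, T), -50.0)
        emissions[:, 1] = 50.0
        assert crf_nll(emissions, params, [1, 1, 1, 1]) == pytest.approx(0.0, abs=1e-9)

    def test_partition_matches_enumeration(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 7))
            T = int(rng.integers(2, 6))
            emissions, params = random_crf(rng, n, T)
            scores = np.array(list(enumerate_scores(emissions, params).values()))
            ref = np.log(np.exp(scores - scores.max()).sum()) + scores.max()
            assert crf_log_partition(emissions, params) == pytest.approx(ref)

    def test_nll_non_negative(self, rng):
        emissions, params = random_crf(rng, 5, 3)
        assert crf_nll(emissions, params, [0, 1, 2, 1, 0]) >= -1e-9

    def test_batched_autograd_matches_scalar(self, rng):
        T = 4
        emissions_np = rng.normal(size=(3, 6, T))
        lengths = np.array([6, 4, 1])
        trans = rng.normal(size=(T, T))
        start = rng.normal(size=T)
        end = rng.normal(size=T)
        paths = rng.integers(0, T, size=(3, 6))
        loss = _crf_nll_batch(nn.Tensor(emissions_np), lengths,
                              nn.Tensor(trans), nn.Tensor(start),
                              nn.Tensor(end), paths)
        params = CrfParams(trans, start, end, tuple(f"t{i}" for i in range(T)))
        ref = np.mean([crf_nll(emissions_np[b, :lengths[b]], params,
                               paths[b, :lengths[b]].tolist())
                       for b in range(3)])
        assert loss.item() == pytest.approx(ref, rel=1e-5)


class TestLegalityBias:
    def test_illegal_moves_penalised(self):
        trans, start, end = bioes_legality_bias(NER_TAGS)
        idx = {t: i for i, t in enumerate(NER_TAGS)}
        assert trans[idx["O"], idx[f"I-{PART}"]] < -1000       # O -> I illegal
        assert trans[idx[f"B-{PART}"], idx["O"]] < -1000        # B -> O illegal
        assert trans[idx[f"B-{PART}"], idx[f"E-{PART}"]] == 0.0
        assert start[idx[f"E-{PART}"]] < -1000
        assert end[idx[f"B-{PART}"]] < -1000
        assert end[idx[f"S-{PART}"]] == 0.0

    def test_decoded_tags_always_legal(self, rng, tiny_corpus):
        vocab = build_vocab(tiny_corpus)
        config = EncoderConfig(hidden_dim=16, n_layers=1, max_length=220,
                               dropout=0.0, seed=5)
        tagger = NerTagger(vocab, config)  # untrained: arbitrary emissions
        for doc in tiny_corpus[:10]:
            tags = tagger.decode(doc.text).tags
            # decoding must never emit an illegal fragment
            from mrispan.corpus_io import bioes_spans
            _, dropped = bioes_spans(tags)
            assert dropped == 0


class TestExtractMentions:
    def test_all_o(self):
        assert extract_mentions(TagSequence("d", ["O", "O"]), "ab") == []

    def test_b_e_mention(self):
        tags = TagSequence("d", [f"B-{PART}", f"E-{PART}", "O"])
        [span] = extract_mentions(tags, "abc")
        assert (span.start, span.end, span.label) == (0, 2, PART)

    def test_round_trip_through_bioes(self, tiny_corpus):
        from mrispan.corpus_io import to_bioes
        from mrispan.corpus_io import ReportDocument, SpanAnnotation
        for doc in tiny_corpus:
            collapsed = ReportDocument(doc.doc_id, doc.text, [
                SpanAnnotation(a.doc_id, a.start, a.end, PART, a.surface)
                for a in doc.annotations])
            mentions = extract_mentions(to_bioes(collapsed), doc.text)
            assert [(m.start, m.end) for m in mentions] == \
                [(a.start, a.end) for a in doc.annotations]


class TestMentionContext:
    def test_contexts_are_text_outside_span(self):
        doc = make_doc("abcdef", [(2, 4, DWI_HIGH)])
        mc = make_context(doc, doc.annotations[0])
        assert mc.left_context == "ab"
        assert mc.right_context == "ef"
        assert mc.full_text == "abcdef"

    def test_windowed_context(self):
        doc = make_doc("0123456789", [(4, 6, DWI_HIGH)])
        mc = make_context(doc, doc.annotations[0], window=2)
        assert mc.full_text == "234567"
        assert (mc.mention.start, mc.mention.end) == (2, 4)

    def test_invalid_context_rejected(self):
        from mrispan.corpus_io import SpanAnnotation
        with pytest.raises(ValueError):
            MentionContext(SpanAnnotation("d", 0, 2, PART, "ab"),
                           "xx", "yy", "abz")


@pytest.fixture(scope="module")
def trained_two_step():
    corpus = generate_corpus(CorpusConfig(
        n_reports=60, target_mean_length=80, max_length=200,
        empty_fraction=0.0, broken_writing_rate=0.0, seed=23))
    enc = EncoderConfig(hidden_dim=32, n_layers=1, n_heads=2, max_length=220,
                        dropout=0.0, seed=1)
    tc = TrainingConfig(learning_rate=3e-3, batch_size=16, epochs=12, seed=1)
    vocab = build_vocab(corpus)
    tagger = train_ner(corpus, encoder_config=enc, training_config=tc,
                       vocab=vocab)
    typer = train_fet(corpus, encoder_config=enc, training_config=tc,
                      vocab=vocab, context_window=50)
    return corpus, tagger, typer


class TestTrainedStages:
    def test_presets_follow_published_table(self):
        assert PRESETS["bilstm_fet"].learning_rate == pytest.approx(1e-3)
        assert PRESETS["bilstm_fet"].batch_size == 256
        assert PRESETS["bilstm_fet"].epochs == 15
        assert PRESETS["bert_fet"].learning_rate == pytest.approx(3e-5)
        assert PRESETS["bert_bilstm_crf"].epochs == 5

    def test_ner_loss_decreases(self, trained_two_step):
        _, tagger, _ = trained_two_step
        assert tagger.history[-1] < tagger.history[0]

    def test_fet_loss_decreases(self, trained_two_step):
        _, _, typer = trained_two_step
        assert typer.history[-1] < typer.history[0]

    def test_ner_one_document_overfit(self):
        doc = make_doc("naoqiao,jizhijiandwigaoxinhao.",
                       [(0, 7, DWI_HIGH), (8, 13, OTHER_PART)])
        enc = EncoderConfig(hidden_dim=32, n_layers=1, n_heads=2, max_length=60,
                            dropout=0.0, seed=2)
        tc = TrainingConfig(learning_rate=5e-3, batch_size=1, epochs=60, seed=2)
        tagger = train_ner([doc], encoder_config=enc, training_config=tc)
        mentions = extract_mentions(tagger.decode(doc.text), doc.text)
        assert [(m.start, m.end) for m in mentions] == [(0, 7), (8, 13)]

    def test_ner_seeded_repeatability(self, tiny_corpus, small_encoder_config,
                                      quick_training_config):
        a = train_ner(tiny_corpus, encoder_config=small_encoder_config,
                      training_config=quick_training_config)
        b = train_ner(tiny_corpus, encoder_config=small_encoder_config,
                      training_config=quick_training_config)
        assert a.history == b.history

    def test_classifier_behavioural_check(self, trained_two_step):
        corpus, _, typer = trained_two_step
        hits = total = 0
        for doc in corpus[:20]:
            for ann in doc.annotations:
                mc = make_context(doc, ann, window=50)
                pred = classify_mention(typer, mc)
                total += 1
                hits += int(pred.label == ann.label)
        assert total > 0
        assert hits / total >= 0.9  # trained typer separates the two types

    def test_zeroed_output_layer_gives_half(self, trained_two_step):
        corpus, _, typer_trained = trained_two_step
        typer = train_fet(corpus[:5], encoder_config=typer_trained.encoder_config,
                          training_config=TrainingConfig(learning_rate=1e-9,
                                                         batch_size=8, epochs=1,
                                                         seed=0),
                          context_window=50)
        typer.out.weight.data[:] = 0.0
        typer.out.bias.data[:] = 0.0
        doc = corpus[0]
        mc = make_context(doc, doc.annotations[0], window=50)
        assert classify_mention(typer, mc).score == pytest.approx(0.5)

    def test_classifier_deterministic(self, trained_two_step):
        corpus, _, typer = trained_two_step
        doc = corpus[0]
        mc = make_context(doc, doc.annotations[0], window=50)
        assert classify_mention(typer, mc).score == \
            classify_mention(typer, mc).score


class TestTwoStepComposition:
    def test_empty_stage_one_output(self, trained_two_step):
        corpus, tagger, typer = trained_two_step
        empty = make_doc("xinhaojunyun.", [])
        # an annotation-free filler sentence should produce no mentions on a
        # trained tagger; even if it does, classification decides the label
        preds = two_step_predict(tagger, typer, empty)
        assert all(p.label == DWI_HIGH for p in preds)

    def test_all_other_part_filtered(self, trained_two_step):
        corpus, tagger, typer = trained_two_step
        preds = two_step_predict(tagger, typer, corpus[0], threshold=1.1)
        assert preds == []  # impossible threshold keeps nothing

    def test_composition_oracle(self, trained_two_step):
        corpus, tagger, typer = trained_two_step
        docs = corpus[:25]
        auto = two_step_predict_corpus(tagger, typer, docs)
        for doc, auto_spans in zip(docs, auto):
            mentions = extract_mentions(tagger.decode(doc.text), doc.text)
            manual = []
            for span in mentions:
                mc = make_context(doc, span, window=typer.context_window)
                if classify_mention(typer, mc).label == DWI_HIGH:
                    manual.append((span.start, span.end))
            assert [(a.start, a.end) for a in auto_spans] == manual

    def test_checkpoint_round_trip(self, trained_two_step, tmp_path):
        corpus, tagger, typer = trained_two_step
        save_two_step(tagger, typer, tmp_path / "ts")
        tagger2, typer2 = load_two_step(tmp_path / "ts")
        a = two_step_predict(tagger, typer, corpus[1])
        b = two_step_predict(tagger2, typer2, corpus[1])
        assert a == b
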