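"""Shared fixtures: tiny corpora and small trained models.

Model-training fixtures are session-scoped and deliberately tiny so the
whole suite stays within a desk-scale CPU budget.
"""

from __future__ import annotations

import numpy as np
import pytest

from mrispan.corpus_io import ReportDocument, SpanAnnotation
from mrispan.encoder import EncoderConfig
from mrispan.synthetic import CorpusConfig, generate_corpus
from mrispan.training import TrainingConfig


@pytest.fixture(scope="session")
def tiny_config() -> CorpusConfig:
    return CorpusConfig(n_reports=30, target_mean_length=80, max_length=200,
                        empty_fraction=0.1, seed=7)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_config) -> list[ReportDocument]:
    return generate_corpus(tiny_config)


@pytest.fixture(scope="session")
def small_corpus() -> list[ReportDocument]:
    return generate_corpus(CorpusConfig(n_reports=100, seed=13))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_encoder_config() -> EncoderConfig:
    return EncoderConfig(hidden_dim=32, n_layers=1, n_heads=2,
                         max_length=220, dropout=0.0, seed=0)


@pytest.fixture(scope="session")
def quick_training_config() -> TrainingConfig:
    return TrainingConfig(learning_rate=3e-3, batch_size=16, epochs=2, seed=0)


def make_doc(text: str, spans: list[tuple[int, int, str]],
             doc_id: str = "d0") -> ReportDocument:
    return ReportDocument(doc_id, text, [
        SpanAnnotation(doc_id, s, e, label, text[s:e]) for s, e, label in spans
    ])
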