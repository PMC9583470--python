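"""Question-conditioned span extraction (the one-step typing model).

The pipeline: lay the input out as ``(CLS, q_1..q_m, SEP, x_1..x_n)``,
encode, project the report rows with two learned d x 2 matrices into
per-character start/end probabilities, binarize by row-argmax, and pair
start and end markers in character order.  Training minimises the sum of
the start- and end-position cross-entropies.

Convention: column 0 of every probability row is the positive ("is a
boundary") class, so a row like [0.8, 0.2] marks a boundary and
[0.3, 0.7] does not.  Argmax ties break to the negative class.
:class:`SpanPair` positions are 1-based inclusive; annotations emitted by
:func:`predict_spans` are converted back to 0-based half-open offsets.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .corpus_io import DWI_HIGH, ReportDocument, SpanAnnotation
from .encoder import (CLS_ID, SEP_ID, CharEncoder, EncodedMatrix, EncoderConfig,
                      Vocabulary, build_vocab, load_weights, save_weights)
from .training import (TrainingConfig, TrainingDivergedError, bucketed_batches,
                       check_finite, pad_batch)

logger = logging.getLogger(__name__)

#: the published extraction question (normalized form)
DEFAULT_QUESTION = "找出报告中dwi高信号部位"

POSITIVE_COLUMN = 0


class QuestionTooLongError(ValueError):
    """The question alone exhausts the maximum input length."""


@dataclass(frozen=True)
class MrcInput:
    """Token layout ``(CLS, q_1..q_m, SEP, x_1..x_n)``."""

    tokens: tuple[int, ...]
    m: int
    n: int

    @property
    def report_offset(self) -> int:
        return self.m + 2

    def __post_init__(self):
        if len(self.tokens) != self.n + self.m + 2:
            raise ValueError("token count must equal n + m + 2")


@dataclass
class PositionProbabilities:
    """n x 2 row-stochastic matrix; ``role`` is 'start' or 'end'."""

    values: np.ndarray
    role: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValueError("PositionProbabilities must be n x 2")
        if np.any(self.values < -1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValueError("probabilities must lie in [0, 1]")
        if not np.allclose(self.values.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows must sum to 1")


@dataclass
class IndicatorSequence:
    """Binarized boundary markers, one per report character."""

    values: np.ndarray
    role: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int64)


@dataclass
class GoldPositionLabels:
    """Binary start/end targets for the positive-class positions."""

    y_start: np.ndarray
    y_end: np.ndarray

    def __post_init__(self):
        self.y_start = np.asarray(self.y_start, dtype=np.int64)
        self.y_end = np.asarray(self.y_end, dtype=np.int64)
        if self.y_start.shape != self.y_end.shape:
            raise ValueError("start/end label lengths differ")


@dataclass(frozen=True)
class SpanPair:
    """A decoded span in 1-based inclusive coordinates."""

    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("span start must not exceed its end")


@dataclass(frozen=True)
class LossValue:
    l_start: float
    l_end: float

    @property
    def total(self) -> float:
        return self.l_start + self.l_end


# ---------------------------------------------------------------------------
# the five pipeline stages
# ---------------------------------------------------------------------------

def build_mrc_input(question: str, report: ReportDocument, vocab: Vocabulary,
                    max_length: int = 400) -> MrcInput:
    """Tokenize question + report into the MRC layout, truncating the report
    so the total length stays within ``max_length``."""
    if not question:
        raise ValueError("question must be nonempty")
    m = len(question)
    room = max_length - m - 2
    if room <= 0 and len(report.text) > 0:
        raise QuestionTooLongError(
            f"question of length {m} leaves no room within max_length {max_length}")
    n = min(len(report.text), max(room, 0))
    if n < len(report.text):
        n_lost = sum(1 for a in report.annotations if a.end > n)
        if n_lost:
            logger.warning("%s: truncation to %d characters drops %d annotation(s)",
                           report.doc_id, n, n_lost)
    tokens = ([CLS_ID] + vocab.encode(question) + [SEP_ID]
              + vocab.encode(report.text[:n]))
    return MrcInput(tuple(tokens), m=m, n=n)


def position_probabilities(E: EncodedMatrix | np.ndarray,
                           T: np.ndarray, role: str = "start") -> PositionProbabilities:
    """Per-row softmax of ``E @ T`` — an n x 2 probability matrix."""
    values = E.values if isinstance(E, EncodedMatrix) else np.asarray(E)
    T = np.asarray(T)
    if values.shape[1] != T.shape[0] or T.shape[1] != 2:
        raise ValueError(
            f"dimension mismatch: E is {values.shape}, T is {T.shape}")
    logits = values @ T
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=1, keepdims=True)
    return PositionProbabilities(probs, role)


def indicators(P: PositionProbabilities) -> IndicatorSequence:
    """Row argmax: 1 where the positive column wins, ties to the negative."""
    positive = P.values[:, POSITIVE_COLUMN] > P.values[:, 1 - POSITIVE_COLUMN]
    return IndicatorSequence(positive.astype(np.int64), P.role)


def match_spans(i_start: IndicatorSequence | Sequence[int],
                i_end: IndicatorSequence | Sequence[int]) -> list[SpanPair]:
    """Pair start and end markers in character order.

    Scanning left to right, each start marker is paired with the earliest
    unused end marker at a position >= it; start markers falling inside a
    completed span and end markers preceding every open start are
    discarded.  The returned pairs are non-overlapping and ordered.
    Positions in the result are 1-based inclusive.
    """
    s = np.asarray(i_start.values if isinstance(i_start, IndicatorSequence) else i_start)
    e = np.asarray(i_end.values if isinstance(i_end, IndicatorSequence) else i_end)
    if s.shape != e.shape:
        raise ValueError("indicator sequences must have equal length")
    starts = np.flatnonzero(s) + 1
    ends = np.flatnonzero(e) + 1
    pairs: list[SpanPair] = []
    si = ei = 0
    while si < len(starts) and ei < len(ends):
        start = starts[si]
        while ei < len(ends) and ends[ei] < start:
            ei += 1
        if ei == len(ends):
            break
        end = ends[ei]
        pairs.append(SpanPair(int(start), int(end)))
        ei += 1
        while si < len(starts) and starts[si] <= end:
            si += 1
    return pairs


def spans_to_gold_labels(doc: ReportDocument,
                         n: int | None = None) -> GoldPositionLabels:
    """Binary start/end targets from the positive-label spans of a document.

    Spans extending past ``n`` (the truncated report length) contribute
    nothing.
    """
    if n is None:
        n = len(doc.text)
    y_start = np.zeros(n, dtype=np.int64)
    y_end = np.zeros(n, dtype=np.int64)
    for ann in doc.annotations:
        if ann.label != DWI_HIGH or ann.end > n:
            continue
        y_start[ann.start] = 1
        y_end[ann.end - 1] = 1
    return GoldPositionLabels(y_start, y_end)


def mrc_loss(p_start: PositionProbabilities, p_end: PositionProbabilities,
             labels: GoldPositionLabels, eps: float = 1e-12) -> LossValue:
    """Two-class cross-entropy per position, averaged, one term per head."""

    def head_loss(P: PositionProbabilities, y: np.ndarray) -> float:
        if P.values.shape[0] != y.shape[0]:
            raise ValueError("probability/label length mismatch")
        picked = np.where(y == 1, P.values[:, POSITIVE_COLUMN],
                          P.values[:, 1 - POSITIVE_COLUMN])
        return float(-np.log(np.clip(picked, eps, 1.0)).mean())

    return LossValue(head_loss(p_start, labels.y_start),
                     head_loss(p_end, labels.y_end))


# ---------------------------------------------------------------------------
# model wrapper, training, prediction
# ---------------------------------------------------------------------------

class MrcModel(nn.Module):
    """Encoder plus the two d x 2 span-head projections."""

    def __init__(self, vocab: Vocabulary, encoder_config: EncoderConfig,
                 question: str = DEFAULT_QUESTION):
        super().__init__()
        self.vocab = vocab
        self.encoder_config = encoder_config
        self.question = question
        self.encoder = CharEncoder(vocab.size, encoder_config)
        rng = np.random.default_rng(encoder_config.seed + 1)
        d = encoder_config.hidden_dim
        self.t_start = nn.Tensor(
            rng.normal(0.0, d ** -0.5, (d, 2)).astype(np.float32), requires_grad=True)
        self.t_end = nn.Tensor(
            rng.normal(0.0, d ** -0.5, (d, 2)).astype(np.float32), requires_grad=True)
        self.history: list[float] = []

    # -- batched forward ----------------------------------------------
    def _forward_logits(self, ids: np.ndarray,
                        lengths: np.ndarray) -> tuple[nn.Tensor, nn.Tensor]:
        H = self.encoder(ids, lengths)
        return H @ self.t_start, H @ self.t_end

    def batch_probabilities(
            self, inputs: Sequence[MrcInput]
    ) -> list[tuple[PositionProbabilities, PositionProbabilities]]:
        """Evaluation-mode start/end probabilities for each report."""
        self.eval()
        ids, lengths = pad_batch([inp.tokens for inp in inputs])
        logits_s, logits_e = self._forward_logits(ids, lengths)
        out = []
        for b, inp in enumerate(inputs):
            rows = slice(inp.report_offset, inp.report_offset + inp.n)
            ps = _softmax_rows(logits_s.data[b, rows])
            pe = _softmax_rows(logits_e.data[b, rows])
            out.append((PositionProbabilities(ps, "start"),
                        PositionProbabilities(pe, "end")))
        return out


def _softmax_rows(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def _batch_loss(model: MrcModel, docs: Sequence[ReportDocument],
                inputs: Sequence[MrcInput],
                positive_weight: float = 1.0) -> nn.Tensor:
    ids, lengths = pad_batch([inp.tokens for inp in inputs])
    B, L = ids.shape
    logits_s, logits_e = model._forward_logits(ids, lengths)
    # class-index targets over the padded grid; positions outside the
    # report span carry zero weight
    cls_s = np.ones((B, L), dtype=np.int64)
    cls_e = np.ones((B, L), dtype=np.int64)
    weight = np.zeros((B, L), dtype=np.float32)
    for b, (doc, inp) in enumerate(zip(docs, inputs)):
        labels = spans_to_gold_labels(doc, n=inp.n)
        rows = slice(inp.report_offset, inp.report_offset + inp.n)
        cls_s[b, rows] = np.where(labels.y_start == 1, POSITIVE_COLUMN,
                                  1 - POSITIVE_COLUMN)
        cls_e[b, rows] = np.where(labels.y_end == 1, POSITIVE_COLUMN,
                                  1 - POSITIVE_COLUMN)
        weight[b, rows] = 1.0
    denom = float(weight.sum())
    b_idx = np.arange(B)[:, None]
    l_idx = np.arange(L)[None, :]
    w_s, w_e = weight, weight
    if positive_weight != 1.0:
        w_s = np.where(cls_s == POSITIVE_COLUMN, positive_weight, 1.0) * weight
        w_e = np.where(cls_e == POSITIVE_COLUMN, positive_weight, 1.0) * weight
    lp_s = nn.log_softmax(logits_s, axis=-1)[b_idx, l_idx, cls_s]
    lp_e = nn.log_softmax(logits_e, axis=-1)[b_idx, l_idx, cls_e]
    loss_s = (lp_s * nn.Tensor(w_s)).sum() * (-1.0 / denom)
    loss_e = (lp_e * nn.Tensor(w_e)).sum() * (-1.0 / denom)
    return loss_s + loss_e


def train_mrc(train_docs: Sequence[ReportDocument],
              question: str = DEFAULT_QUESTION,
              encoder_config: EncoderConfig | None = None,
              training_config: TrainingConfig | None = None,
              vocab: Vocabulary | None = None,
              positive_weight: float = 1.0) -> MrcModel:
    """Train the span extractor; deterministic for a fixed seed.

    Per-epoch mean losses are recorded in ``model.history``.  A non-finite
    loss aborts with :class:`TrainingDivergedError`.  ``positive_weight``
    optionally up-weights the sparse boundary class in the cross-entropy;
    it defaults to off (plain cross-entropy).
    """
    if not train_docs:
        raise ValueError("training corpus is empty")
    encoder_config = encoder_config or EncoderConfig()
    tc = training_config or TrainingConfig()
    if vocab is None:
        vocab = build_vocab(train_docs, extra_texts=[question])
    model = MrcModel(vocab, encoder_config, question)
    inputs = [build_mrc_input(question, doc, vocab, encoder_config.max_length)
              for doc in train_docs]
    opt = nn.Adam(model.parameters(), lr=tc.learning_rate)
    rng = np.random.default_rng(tc.seed)
    model.train()
    doc_lengths = [len(inp.tokens) for inp in inputs]
    steps_per_epoch = -(-len(train_docs) // tc.batch_size)
    total_steps = steps_per_epoch * tc.epochs
    step = 0
    for epoch in range(tc.epochs):
        total, n_batches = 0.0, 0
        for batch in bucketed_batches(doc_lengths, tc.batch_size, rng):
            loss = _batch_loss(model, [train_docs[i] for i in batch],
                               [inputs[i] for i in batch], positive_weight)
            value = loss.item()
            check_finite(value, f"epoch {epoch + 1}")
            opt.zero_grad()
            loss.backward()
            nn.clip_grad_norm(model.parameters(), tc.grad_clip)
            opt.lr = tc.lr_at(step, total_steps)
            opt.step()
            step += 1
            total += value
            n_batches += 1
        model.history.append(total / n_batches)
    model.eval()
    return model


def predict_spans(model: MrcModel, report: ReportDocument,
                  question: str | None = None) -> list[SpanAnnotation]:
    """Run the full pipeline on one report and emit positive-label spans."""
    return predict_corpus(model, [report], question=question)[0]


def predict_corpus(model: MrcModel, reports: Sequence[ReportDocument],
                   question: str | None = None,
                   batch_size: int = 64) -> list[list[SpanAnnotation]]:
    """Batched prediction; one annotation list per input report."""
    question = question or model.question
    results: list[list[SpanAnnotation]] = [[] for _ in reports]
    # visit in length order so padded batches stay tight
    order = sorted(range(len(reports)), key=lambda i: len(reports[i].text))
    for lo in range(0, len(order), batch_size):
        chunk_idx = order[lo:lo + batch_size]
        chunk = [reports[i] for i in chunk_idx]
        nonempty = [r for r in chunk if r.text]
        inputs = [build_mrc_input(question, r, model.vocab,
                                  model.encoder_config.max_length)
                  for r in nonempty]
        probs = model.batch_probabilities(inputs) if inputs else []
        chunk_preds: list[list[SpanAnnotation]] = [[] for _ in chunk]
        positions = [i for i, r in enumerate(chunk) if r.text]
        for idx, (ps, pe) in zip(positions, probs):
            report = chunk[idx]
            pairs = match_spans(indicators(ps), indicators(pe))
            chunk_preds[idx] = [
                SpanAnnotation(report.doc_id, pair.start - 1, pair.end, DWI_HIGH,
                               report.text[pair.start - 1:pair.end])
                for pair in pairs
            ]
        for i, preds in zip(chunk_idx, chunk_preds):
            results[i] = preds
    return results


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_mrc(model: MrcModel, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    model.vocab.save(directory / "vocab.txt")
    save_weights(model, directory / "weights.npz")
    meta = {
        "question": model.question,
        "encoder_config": dataclasses.asdict(model.encoder_config),
        "history": model.history,
    }
    (directory / "model.json").write_text(json.dumps(meta, ensure_ascii=False,
                                                     indent=2), encoding="utf-8")


def load_mrc(directory) -> MrcModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text(encoding="utf-8"))
    vocab = Vocabulary.load(directory / "vocab.txt")
    config = EncoderConfig(**meta["encoder_config"])
    model = MrcModel(vocab, config, meta["question"])
    load_weights(model, directory / "weights.npz")
    model.history = list(meta.get("history", []))
    model.eval()
    return model
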