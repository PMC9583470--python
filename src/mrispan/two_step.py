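"""Two-step baseline: BIOES sequence labelling then mention typing.

Stage 1 tags every body-part mention with a single generic label using an
encoder + linear-chain CRF; stage 2 classifies each recognised mention as
a diffusion-high finding or an ordinary part from concatenated mention
and context representations.  Composing the stages lets recognition
errors propagate, which is exactly the failure mode the one-step model is
meant to avoid — the evaluation suite checks that this accumulation is
observable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import nn
from .corpus_io import (DWI_HIGH, OTHER_PART, PART, ReportDocument,
                        SpanAnnotation, TagSequence, bioes_spans, to_bioes)
from .encoder import CharEncoder, EncoderConfig, Vocabulary, build_vocab, \
    load_weights, save_weights
from .training import (TrainingConfig, bucketed_batches, check_finite,
                       pad_batch)

logger = logging.getLogger(__name__)

#: stage-1 tag inventory over the single generic mention label
NER_TAGS = ("O", f"B-{PART}", f"I-{PART}", f"E-{PART}", f"S-{PART}")

_ILLEGAL = -1e4  # additive penalty enforcing BIOES-legal transitions


@dataclass
class CrfParams:
    """Linear-chain CRF parameters over an ordered tag vocabulary."""

    transitions: np.ndarray           # (T, T): score of tag i -> tag j
    start: np.ndarray                 # (T,): BOS -> tag
    end: np.ndarray                   # (T,): tag -> EOS
    tag_vocab: tuple[str, ...]

    def __post_init__(self):
        T = len(self.tag_vocab)
        self.transitions = np.asarray(self.transitions, dtype=np.float64)
        self.start = np.asarray(self.start, dtype=np.float64)
        self.end = np.asarray(self.end, dtype=np.float64)
        if self.transitions.shape != (T, T):
            raise ValueError("transition matrix must be square over tag_vocab")
        if self.start.shape != (T,) or self.end.shape != (T,):
            raise ValueError("start/end scores must have one entry per tag")


@dataclass(frozen=True)
class MentionContext:
    """A mention of unknown type plus the text around it."""

    mention: SpanAnnotation
    left_context: str
    right_context: str
    full_text: str

    def __post_init__(self):
        expected = (self.full_text[:self.mention.start],
                    self.full_text[self.mention.end:])
        if (self.left_context, self.right_context) != expected:
            raise ValueError("contexts must be the text outside the mention span")


@dataclass(frozen=True)
class TypePrediction:
    label: str
    score: float  # probability of the positive (DWI_HIGH) class

    def __post_init__(self):
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


# ---------------------------------------------------------------------------
# linear-chain CRF primitives (NumPy contract versions)
# ---------------------------------------------------------------------------

def crf_score(emissions: np.ndarray, params: CrfParams,
              path: Sequence[int]) -> float:
    """Emission + transition score of one tag path, including BOS/EOS."""
    emissions = np.asarray(emissions, dtype=np.float64)
    n, T = emissions.shape
    if len(path) != n:
        raise ValueError("path length must match the emission rows")
    if any(not 0 <= t < T for t in path):
        raise ValueError("tag index out of range")
    score = params.start[path[0]] + params.end[path[-1]]
    score += sum(emissions[i, t] for i, t in enumerate(path))
    score += sum(params.transitions[path[i - 1], path[i]] for i in range(1, n))
    return float(score)


def crf_log_partition(emissions: np.ndarray, params: CrfParams) -> float:
    """log sum over all paths of exp(score), via the forward recursion."""
    emissions = np.asarray(emissions, dtype=np.float64)
    alpha = params.start + emissions[0]
    for t in range(1, emissions.shape[0]):
        alpha = _logsumexp_np(alpha[:, None] + params.transitions, axis=0) + emissions[t]
    return float(_logsumexp_np(alpha + params.end, axis=0))


def crf_nll(emissions: np.ndarray, params: CrfParams,
            path: Sequence[int]) -> float:
    """Negative log-likelihood: log-partition minus the gold-path score."""
    return crf_log_partition(emissions, params) - crf_score(emissions, params, path)


def crf_viterbi(emissions: np.ndarray, params: CrfParams) -> list[int]:
    """An argmax-scoring path; ties break to the lower tag index."""
    emissions = np.asarray(emissions, dtype=np.float64)
    n, T = emissions.shape
    score = params.start + emissions[0]
    back = np.zeros((n, T), dtype=np.int64)
    for t in range(1, n):
        cand = score[:, None] + params.transitions
        back[t] = cand.argmax(axis=0)
        score = cand.max(axis=0) + emissions[t]
    score = score + params.end
    path = [int(score.argmax())]
    for t in range(n - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    return path[::-1]


def _logsumexp_np(a: np.ndarray, axis: int) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    out = np.log(np.exp(a - m).sum(axis=axis)) + np.squeeze(m, axis=axis)
    return out


def bioes_legality_bias(tag_vocab: Sequence[str] = NER_TAGS
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Additive (transition, start, end) penalties ruling out illegal
    BIOES moves: B must be followed by I/E, I by I/E, and entities must
    close before O/B/S or the end of the sequence."""
    T = len(tag_vocab)
    trans = np.zeros((T, T))
    start = np.zeros(T)
    end = np.zeros(T)
    prefix = [t.partition("-")[0] for t in tag_vocab]
    closing = {"O", "E", "S"}     # states with no entity left open
    opening = {"O", "B", "S"}     # tags allowed after a closed state
    for i, p in enumerate(prefix):
        if p in {"I", "E"}:
            start[i] = _ILLEGAL
        if p in {"B", "I"}:
            end[i] = _ILLEGAL
        for j, q in enumerate(prefix):
            legal = (q in {"I", "E"}) if p in {"B", "I"} else (q in opening)
            if p in closing:
                legal = q in opening
            if not legal:
                trans[i, j] = _ILLEGAL
    return trans, start, end


# ---------------------------------------------------------------------------
# batched CRF loss on autograd tensors (used for training)
# ---------------------------------------------------------------------------

def _crf_nll_batch(emissions: nn.Tensor, lengths: np.ndarray,
                   trans: nn.Tensor, start: nn.Tensor, end: nn.Tensor,
                   paths: np.ndarray) -> nn.Tensor:
    """Mean per-sequence NLL over a padded batch."""
    B, L, T = emissions.data.shape
    mask = (np.arange(L)[None, :] < lengths[:, None])
    # forward recursion with per-position freezing past each length
    alpha = start.reshape((1, T)) + emissions[:, 0]
    for t in range(1, L):
        scores = alpha.reshape((B, T, 1)) + trans.reshape((1, T, T)) \
            + emissions[:, t].reshape((B, 1, T))
        new = nn.logsumexp(scores, axis=1)
        m = nn.Tensor(mask[:, t:t + 1].astype(np.float32))
        alpha = new * m + alpha * (1.0 - m)
    log_z = nn.logsumexp(alpha + end.reshape((1, T)), axis=1)  # (B,)

    # gold-path score via flat gathers over the valid positions
    b_idx, t_idx = np.nonzero(mask)
    gold = emissions[b_idx, t_idx, paths[b_idx, t_idx]].sum()
    pair_mask = mask[:, 1:] & mask[:, :-1]
    pb, pt = np.nonzero(pair_mask)
    if len(pb):
        gold = gold + trans[paths[pb, pt], paths[pb, pt + 1]].sum()
    gold = gold + start[paths[:, 0]].sum()
    last = lengths - 1
    gold = gold + end[paths[np.arange(B), last]].sum()
    return (log_z.sum() - gold) * (1.0 / B)


# ---------------------------------------------------------------------------
# stage 1: the mention tagger
# ---------------------------------------------------------------------------

class NerTagger(nn.Module):
    """Character encoder + emission projection + CRF over BIOES tags."""

    def __init__(self, vocab: Vocabulary, encoder_config: EncoderConfig):
        super().__init__()
        self.vocab = vocab
        self.encoder_config = encoder_config
        self.encoder = CharEncoder(vocab.size, encoder_config)
        rng = np.random.default_rng(encoder_config.seed + 2)
        T = len(NER_TAGS)
        self.emit = nn.Linear(encoder_config.hidden_dim, T, rng)
        self.trans = nn.Tensor(np.zeros((T, T), dtype=np.float32), requires_grad=True)
        self.start = nn.Tensor(np.zeros(T, dtype=np.float32), requires_grad=True)
        self.end = nn.Tensor(np.zeros(T, dtype=np.float32), requires_grad=True)
        bias = bioes_legality_bias(NER_TAGS)
        self._bias_trans = bias[0].astype(np.float32)
        self._bias_start = bias[1].astype(np.float32)
        self._bias_end = bias[2].astype(np.float32)
        self.history: list[float] = []

    def crf_params(self) -> CrfParams:
        """Learned parameters with the legality mask folded in."""
        return CrfParams(self.trans.data + self._bias_trans,
                         self.start.data + self._bias_start,
                         self.end.data + self._bias_end, NER_TAGS)

    def _emissions(self, ids: np.ndarray, lengths: np.ndarray) -> nn.Tensor:
        return self.emit(self.encoder(ids, lengths))

    def decode(self, text: str) -> TagSequence:
        return self.decode_batch([ReportDocument("", text)])[0]

    def decode_batch(self, docs: Sequence[ReportDocument]) -> list[TagSequence]:
        self.eval()
        max_len = self.encoder_config.max_length
        texts = [doc.text[:max_len] for doc in docs]
        ids, lengths = pad_batch([self.vocab.encode(t) for t in texts])
        if ids.shape[1] == 0:
            return [TagSequence(doc.doc_id, ["O"] * len(doc.text)) for doc in docs]
        emissions = self._emissions(ids, lengths).data
        params = self.crf_params()
        out = []
        for b, doc in enumerate(docs):
            n = int(lengths[b])
            tags = [NER_TAGS[t] for t in
                    crf_viterbi(emissions[b, :n], params)] if n else []
            tags += ["O"] * (len(doc.text) - len(tags))  # truncated tail
            out.append(TagSequence(doc.doc_id, tags))
        return out


def _gold_tag_ids(doc: ReportDocument, max_len: int) -> np.ndarray:
    collapsed = ReportDocument(
        doc.doc_id, doc.text,
        [SpanAnnotation(a.doc_id, a.start, a.end, PART, a.surface)
         for a in doc.annotations if a.end <= max_len])
    tags = to_bioes(collapsed).tags[:max_len]
    index = {tag: i for i, tag in enumerate(NER_TAGS)}
    return np.array([index[t] for t in tags], dtype=np.int64)


def train_ner(train_docs: Sequence[ReportDocument],
              encoder_config: EncoderConfig | None = None,
              training_config: TrainingConfig | None = None,
              vocab: Vocabulary | None = None) -> NerTagger:
    """Train the stage-1 tagger on all mentions, both labels collapsed."""
    if not train_docs:
        raise ValueError("training corpus is empty")
    encoder_config = encoder_config or EncoderConfig()
    tc = training_config or TrainingConfig()
    vocab = vocab or build_vocab(train_docs)
    tagger = NerTagger(vocab, encoder_config)
    max_len = encoder_config.max_length
    token_ids = [vocab.encode(doc.text[:max_len]) for doc in train_docs]
    gold = [_gold_tag_ids(doc, max_len) for doc in train_docs]
    opt = nn.Adam(tagger.parameters(), lr=tc.learning_rate)
    rng = np.random.default_rng(tc.seed)
    bias_t = nn.Tensor(tagger._bias_trans)
    bias_s = nn.Tensor(tagger._bias_start)
    bias_e = nn.Tensor(tagger._bias_end)
    tagger.train()
    doc_lengths = [len(t) for t in token_ids]
    for epoch in range(tc.epochs):
        total, n_batches = 0.0, 0
        for batch in bucketed_batches(doc_lengths, tc.batch_size, rng):
            batch = [i for i in batch if len(token_ids[i])]
            if not batch:
                continue
            ids, lengths = pad_batch([token_ids[i] for i in batch])
            paths = np.zeros(ids.shape, dtype=np.int64)
            for row, i in enumerate(batch):
                paths[row, :len(gold[i])] = gold[i]
            emissions = tagger._emissions(ids, lengths)
            loss = _crf_nll_batch(emissions, lengths, tagger.trans + bias_t,
                                  tagger.start + bias_s, tagger.end + bias_e,
                                  paths)
            value = loss.item()
            check_finite(value, f"NER epoch {epoch + 1}")
            opt.zero_grad()
            loss.backward()
            nn.clip_grad_norm(tagger.parameters(), tc.grad_clip)
            opt.step()
            total += value
            n_batches += 1
        tagger.history.append(total / max(n_batches, 1))
    tagger.eval()
    return tagger


def extract_mentions(tags: TagSequence, text: str) -> list[SpanAnnotation]:
    """Label-agnostic mention spans from a BIOES tag sequence."""
    if len(tags.tags) != len(text):
        raise ValueError("tag/text length mismatch")
    spans, dropped = bioes_spans(tags.tags)
    if dropped:
        logger.debug("%s: %d illegal fragment(s) dropped", tags.doc_id, dropped)
    return [SpanAnnotation(tags.doc_id, s, e, PART, text[s:e])
            for s, e, _ in spans]


# ---------------------------------------------------------------------------
# stage 2: the mention typer
# ---------------------------------------------------------------------------

def make_context(doc: ReportDocument, span: SpanAnnotation,
                 window: int | None = None) -> MentionContext:
    """Build a mention-plus-context view, optionally window-limited."""
    if span.start >= span.end:
        raise ValueError("empty mention")
    if window is None:
        lo, hi = 0, len(doc.text)
    else:
        lo, hi = max(0, span.start - window), min(len(doc.text), span.end + window)
    mention = SpanAnnotation(span.doc_id, span.start - lo, span.end - lo,
                             span.label, span.surface)
    full = doc.text[lo:hi]
    return MentionContext(mention, full[:mention.start], full[mention.end:], full)


class MentionTyper(nn.Module):
    """Pooled mention and context representations -> two-way prediction."""

    def __init__(self, vocab: Vocabulary, encoder_config: EncoderConfig,
                 context_window: int | None = None):
        super().__init__()
        self.vocab = vocab
        self.encoder_config = encoder_config
        self.context_window = context_window
        self.encoder = CharEncoder(vocab.size, encoder_config)
        rng = np.random.default_rng(encoder_config.seed + 3)
        self.out = nn.Linear(2 * encoder_config.hidden_dim, 2, rng)
        self.history: list[float] = []

    def _logits(self, contexts: Sequence[MentionContext]) -> nn.Tensor:
        max_len = self.encoder_config.max_length
        ids, lengths = pad_batch(
            [self.vocab.encode(mc.full_text[:max_len]) for mc in contexts])
        B, L = ids.shape
        H = self.encoder(ids, lengths)
        m_mask = np.zeros((B, L, 1), dtype=np.float32)
        c_mask = np.zeros((B, L, 1), dtype=np.float32)
        for b, mc in enumerate(contexts):
            n = int(lengths[b])
            m_mask[b, mc.mention.start:min(mc.mention.end, n), 0] = 1.0
            c_mask[b, :n, 0] = 1.0
        c_mask = c_mask - m_mask
        m_cnt = np.maximum(m_mask.sum(axis=1), 1.0)
        c_cnt = np.maximum(c_mask.sum(axis=1), 1.0)
        m_vec = (H * nn.Tensor(m_mask)).sum(axis=1) * nn.Tensor(1.0 / m_cnt)
        c_vec = (H * nn.Tensor(c_mask)).sum(axis=1) * nn.Tensor(1.0 / c_cnt)
        return self.out(nn.concat([m_vec, c_vec], axis=-1))

    def predict(self, contexts: Sequence[MentionContext],
                threshold: float = 0.5) -> list[TypePrediction]:
        self.eval()
        if not contexts:
            return []
        logits = self._logits(contexts).data
        shifted = logits - logits.max(axis=-1, keepdims=True)
        probs = np.exp(shifted)
        probs /= probs.sum(axis=-1, keepdims=True)
        out = []
        for p in probs[:, 0]:  # column 0 = positive class
            label = DWI_HIGH if p >= threshold else OTHER_PART
            out.append(TypePrediction(label, float(p)))
        return out


def classify_mention(model: MentionTyper, mc: MentionContext,
                     threshold: float = 0.5) -> TypePrediction:
    return model.predict([mc], threshold=threshold)[0]


def train_fet(train_docs: Sequence[ReportDocument],
              encoder_config: EncoderConfig | None = None,
              training_config: TrainingConfig | None = None,
              vocab: Vocabulary | None = None,
              context_window: int | None = None) -> MentionTyper:
    """Train the stage-2 typer on gold mentions with their gold types."""
    if not train_docs:
        raise ValueError("training corpus is empty")
    encoder_config = encoder_config or EncoderConfig()
    tc = training_config or TrainingConfig()
    vocab = vocab or build_vocab(train_docs)
    typer = MentionTyper(vocab, encoder_config, context_window)
    contexts: list[MentionContext] = []
    targets: list[int] = []
    for doc in train_docs:
        for ann in doc.annotations:
            contexts.append(make_context(doc, ann, window=context_window))
            targets.append(0 if ann.label == DWI_HIGH else 1)  # column 0 positive
    if not contexts:
        raise ValueError("no annotated mentions to train on")
    targets_arr = np.array(targets, dtype=np.int64)
    opt = nn.Adam(typer.parameters(), lr=tc.learning_rate)
    rng = np.random.default_rng(tc.seed)
    typer.train()
    ctx_lengths = [len(mc.full_text) for mc in contexts]
    for epoch in range(tc.epochs):
        total, n_batches = 0.0, 0
        for batch in bucketed_batches(ctx_lengths, tc.batch_size, rng):
            logits = typer._logits([contexts[i] for i in batch])
            logp = nn.log_softmax(logits, axis=-1)
            picked = logp[np.arange(len(batch)), targets_arr[batch]]
            loss = picked.sum() * (-1.0 / len(batch))
            value = loss.item()
            check_finite(value, f"FET epoch {epoch + 1}")
            opt.zero_grad()
            loss.backward()
            nn.clip_grad_norm(typer.parameters(), tc.grad_clip)
            opt.step()
            total += value
            n_batches += 1
        typer.history.append(total / max(n_batches, 1))
    typer.eval()
    return typer


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def two_step_predict(tagger: NerTagger, typer: MentionTyper,
                     report: ReportDocument,
                     threshold: float = 0.5) -> list[SpanAnnotation]:
    return two_step_predict_corpus(tagger, typer, [report], threshold)[0]


def two_step_predict_corpus(tagger: NerTagger, typer: MentionTyper,
                            reports: Sequence[ReportDocument],
                            threshold: float = 0.5,
                            batch_size: int = 64) -> list[list[SpanAnnotation]]:
    """Stage-1 mentions classified by stage 2; positive mentions retained."""
    results: list[list[SpanAnnotation]] = [[] for _ in reports]
    order = sorted(range(len(reports)), key=lambda i: len(reports[i].text))
    for lo in range(0, len(order), batch_size):
        chunk_idx = order[lo:lo + batch_size]
        chunk = [reports[i] for i in chunk_idx]
        tag_seqs = tagger.decode_batch(chunk)
        mentions_per_doc = [extract_mentions(ts, doc.text)
                            for ts, doc in zip(tag_seqs, chunk)]
        flat_contexts = []
        owners = []
        for i, (doc, mentions) in enumerate(zip(chunk, mentions_per_doc)):
            for span in mentions:
                flat_contexts.append(make_context(doc, span,
                                                  window=typer.context_window))
                owners.append((i, span))
        preds = typer.predict(flat_contexts, threshold=threshold)
        chunk_out: list[list[SpanAnnotation]] = [[] for _ in chunk]
        for (i, span), pred in zip(owners, preds):
            if pred.label == DWI_HIGH:
                chunk_out[i].append(SpanAnnotation(
                    span.doc_id, span.start, span.end, DWI_HIGH, span.surface))
        for i, preds_i in zip(chunk_idx, chunk_out):
            results[i] = preds_i
    return results


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_two_step(tagger: NerTagger, typer: MentionTyper, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    tagger.vocab.save(directory / "vocab.txt")
    save_weights(tagger, directory / "ner_weights.npz")
    save_weights(typer, directory / "fet_weights.npz")
    meta = {
        "ner_encoder_config": _cfg_dict(tagger.encoder_config),
        "fet_encoder_config": _cfg_dict(typer.encoder_config),
        "context_window": typer.context_window,
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2),
                                          encoding="utf-8")


def load_two_step(directory) -> tuple[NerTagger, MentionTyper]:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text(encoding="utf-8"))
    vocab = Vocabulary.load(directory / "vocab.txt")
    tagger = NerTagger(vocab, EncoderConfig(**meta["ner_encoder_config"]))
    load_weights(tagger, directory / "ner_weights.npz")
    typer = MentionTyper(vocab, EncoderConfig(**meta["fet_encoder_config"]),
                         meta.get("context_window"))
    load_weights(typer, directory / "fet_weights.npz")
    tagger.eval()
    typer.eval()
    return tagger, typer


def _cfg_dict(config: EncoderConfig) -> dict:
    import dataclasses
    return dataclasses.asdict(config)
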