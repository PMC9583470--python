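"""Generator for annotated MRI-report-like corpora.

The generated texts reproduce the statistical profile the extractors are
benchmarked on (mention counts, length distribution, empty-description
fraction) and the central linguistic difficulty: several imaging
sequences reporting signals over the same body parts, so that whether a
part is a diffusion-high finding depends on the statement around it, not
on the part string itself.

Templates are language-agnostic character patterns with pluggable
vocabularies.  The bundled default pack uses romanized tokens so tests
need no CJK handling; :func:`cjk_vocabulary` mirrors Chinese phrasing.
Counts are Poisson and target lengths truncated-normal — modelling
choices, not corpus facts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .corpus_io import DWI_HIGH, OTHER_PART, ReportDocument, SpanAnnotation

STATEMENT_KINDS = ("dwi_high", "distractor", "multi_modality")

_DEFAULT_PARTS = (
    "naoqiao", "fangsheguan", "jizhi", "jidijie", "banluanyuan",
    "xiaonao", "dingye", "nieye", "zhenye", "haima", "shiqiu",
    "neinang", "wainang", "danaojiao", "qianye", "huizhiti",
)

_DEFAULT_MODALITIES = ("dwi", "flair", "t2wi", "t1wi")

_DEFAULT_DESCRIPTORS = ("gao", "shaogao", "chang", "deng")

#: modality/descriptor pairs that must NOT be read as diffusion-high
_DISTRACTOR_SIGNALS = (
    ("flair", "gao"), ("flair", "shaogao"), ("t2wi", "chang"),
    ("t1wi", "chang"), ("dwi", "deng"), ("t2wi", "gao"),
)

_FILLERS = (
    "saomiaoxulieweijianyichang.",
    "zhongxianwuyiwei.",
    "gejiegouxingtaizhengchang.",
    "weijianmingxianzhanweixiaoying.",
    "saomiaofanweineixinhaojunyun.",
    "xingtaidaxiaoweijianyichang.",
)


@dataclass(frozen=True)
class CorpusConfig:
    """Knobs of the generator; defaults follow the target corpus profile."""

    n_reports: int = 100
    empty_fraction: float = 0.1
    mean_dwi_mentions: float = 2.0
    mean_other_mentions: float = 8.0
    target_mean_length: int = 170
    max_length: int = 525
    part_vocabulary: tuple[str, ...] = _DEFAULT_PARTS
    modality_vocabulary: tuple[str, ...] = _DEFAULT_MODALITIES
    descriptor_vocabulary: tuple[str, ...] = _DEFAULT_DESCRIPTORS
    shared_part_rate: float = 0.3
    broken_writing_rate: float = 0.05
    max_parts_per_statement: int = 3
    seed: int = 0

    def __post_init__(self):
        for name in ("empty_fraction", "shared_part_rate", "broken_writing_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.mean_dwi_mentions <= 0 or self.mean_other_mentions <= 0:
            raise ValueError("mention means must be positive")
        if self.max_length < self.target_mean_length:
            raise ValueError("max_length must be >= target_mean_length")
        if not self.part_vocabulary or not self.modality_vocabulary \
                or not self.descriptor_vocabulary:
            raise ValueError("vocabularies must be nonempty")
        if self.max_parts_per_statement < 1:
            raise ValueError("max_parts_per_statement must be >= 1")


@dataclass(frozen=True)
class SummaryStats:
    """Empirical corpus summaries (mention means are per non-empty report)."""

    mean_dwi_mentions: float
    mean_other_mentions: float
    mean_length: float
    max_length: int
    empty_fraction: float


def cjk_vocabulary() -> dict[str, tuple[str, ...]]:
    """A CJK vocabulary pack mirroring real report phrasing."""
    return {
        "part_vocabulary": ("脑桥", "放射冠", "基底节", "半卵圆中心", "小脑",
                            "顶叶", "颞叶", "枕叶", "海马", "丘脑", "内囊",
                            "外囊", "大脑脚", "额叶", "胼胝体"),
        "modality_vocabulary": ("dwi", "flair", "t2wi", "t1wi"),
        "descriptor_vocabulary": ("高", "稍高", "长", "等"),
    }


def _sample_parts(rng: np.random.Generator, config: CorpusConfig,
                  k: int) -> list[str]:
    vocab = config.part_vocabulary
    k = min(k, len(vocab))
    idx = rng.choice(len(vocab), size=k, replace=False)
    return [vocab[i] for i in idx]


def _part_list_fragment(parts: Sequence[str], broken: bool) -> tuple[str, list[tuple[int, int, str]]]:
    """Concatenate parts, recording each part's span relative to offset 0."""
    sep = "" if broken else ","
    spans: list[tuple[int, int, str]] = []
    pieces: list[str] = []
    pos = 0
    for i, part in enumerate(parts):
        if i:
            pieces.append(sep)
            pos += len(sep)
        spans.append((pos, pos + len(part), part))
        pieces.append(part)
        pos += len(part)
    return "".join(pieces), spans


def generate_statement(
    rng: np.random.Generator,
    kind: str,
    config: CorpusConfig | None = None,
    n_parts: int | None = None,
) -> tuple[str, list[SpanAnnotation]]:
    """Produce one statement fragment and its annotations (offsets from 0).

    ``dwi_high`` statements attribute a high diffusion signal to their
    parts; ``distractor`` statements attribute a non-target signal (e.g.
    FLAIR-high, T2WI-long, DWI-equal); ``multi_modality`` statements list
    the same parts under two or more modalities and the parts are labelled
    by whether a diffusion-high attribution is among them.
    """
    config = config or CorpusConfig()
    if kind not in STATEMENT_KINDS:
        raise ValueError(f"unknown statement kind {kind!r}")
    if n_parts is None:
        n_parts = int(rng.integers(1, config.max_parts_per_statement + 1))
    parts = _sample_parts(rng, config, n_parts)
    broken = rng.random() < config.broken_writing_rate
    part_text, part_spans = _part_list_fragment(parts, broken)

    if kind == "dwi_high":
        signals = ["dwigaoxinhao"]
        positive = True
    elif kind == "distractor":
        mod, desc = _DISTRACTOR_SIGNALS[rng.integers(len(_DISTRACTOR_SIGNALS))]
        signals = [f"{mod}{desc}xinhao"]
        positive = False
    else:  # multi_modality: >= 2 signals over the same part list
        positive = bool(rng.random() < 0.5)
        chosen = [_DISTRACTOR_SIGNALS[i] for i in
                  rng.choice(len(_DISTRACTOR_SIGNALS), size=2, replace=False)]
        signals = [f"{m}{d}xinhao" for m, d in chosen]
        if positive:
            signals[rng.integers(len(signals))] = "dwigaoxinhao"

    fragment = part_text + "kejian" + "ji".join(signals) + "."
    label = DWI_HIGH if positive else OTHER_PART
    annotations = [
        SpanAnnotation("", start, end, label, surface)
        for start, end, surface in part_spans
    ]
    return fragment, annotations


def generate_report(config: CorpusConfig, rng: np.random.Generator,
                    doc_id: str = "r0") -> ReportDocument:
    """Compose one report from statements and neutral filler sentences."""
    target_len = int(np.clip(rng.normal(config.target_mean_length, 55),
                             20, config.max_length))
    pieces: list[str] = []
    annotations: list[SpanAnnotation] = []
    pos = 0

    def append(fragment: str, anns: Sequence[SpanAnnotation]) -> None:
        nonlocal pos
        pieces.append(fragment)
        for ann in anns:
            annotations.append(replace(ann, doc_id=doc_id,
                                       start=ann.start + pos, end=ann.end + pos))
        pos += len(fragment)

    if rng.random() >= config.empty_fraction:
        n_dwi = int(rng.poisson(config.mean_dwi_mentions))
        n_other = int(rng.poisson(config.mean_other_mentions))
        while (n_dwi > 0 or n_other > 0) and pos < config.max_length - 60:
            multi = rng.random() < config.shared_part_rate
            if multi and n_dwi > 0 and rng.random() < 0.5:
                kind, budget = "multi_modality", n_dwi
            elif multi and n_other > 0:
                kind, budget = "multi_modality", n_other
            elif n_dwi > 0 and (n_other == 0 or rng.random() < n_dwi / (n_dwi + n_other)):
                kind, budget = "dwi_high", n_dwi
            else:
                kind, budget = "distractor", n_other
            k = int(min(rng.integers(1, config.max_parts_per_statement + 1), budget))
            fragment, anns = generate_statement(rng, kind, config, n_parts=k)
            if kind == "multi_modality":
                # the draw inside generate_statement decides polarity; respect budgets
                is_pos = anns and anns[0].label == DWI_HIGH
                if is_pos and k > n_dwi or (not is_pos) and k > n_other:
                    continue
            if pos + len(fragment) > config.max_length:
                break
            append(fragment, anns)
            got_pos = sum(1 for a in anns if a.label == DWI_HIGH)
            n_dwi -= got_pos
            n_other -= len(anns) - got_pos

    filler_order = rng.permutation(len(_FILLERS))
    for idx in np.tile(filler_order, 4):
        filler = _FILLERS[idx]
        if pos >= target_len or pos + len(filler) > config.max_length:
            break
        append(filler, ())

    if pos == 0:  # degenerate config; keep documents nonempty
        append(_FILLERS[0][:config.max_length], ())
    return ReportDocument(doc_id, "".join(pieces), annotations)


def generate_corpus(config: CorpusConfig) -> list[ReportDocument]:
    """Generate ``config.n_reports`` documents, reproducibly.

    Report-level RNG streams are derived from ``(seed, counter)`` so any
    report can be regenerated independently of the others.
    """
    docs = []
    for i in range(config.n_reports):
        rng = np.random.default_rng([config.seed, i])
        docs.append(generate_report(config, rng, doc_id=f"r{i:05d}"))
    return docs


def corpus_stats(corpus: Sequence[ReportDocument]) -> SummaryStats:
    """Exact empirical summaries of an annotated corpus."""
    if not corpus:
        raise ValueError("empty corpus")
    lengths = [len(doc.text) for doc in corpus]
    non_empty = [doc for doc in corpus if doc.annotations]
    if non_empty:
        dwi = [sum(1 for a in d.annotations if a.label == DWI_HIGH) for d in non_empty]
        other = [sum(1 for a in d.annotations if a.label == OTHER_PART)
                 for d in non_empty]
        mean_dwi = float(np.mean(dwi))
        mean_other = float(np.mean(other))
    else:
        mean_dwi = mean_other = 0.0
    return SummaryStats(
        mean_dwi_mentions=mean_dwi,
        mean_other_mentions=mean_other,
        mean_length=float(np.mean(lengths)),
        max_length=int(np.max(lengths)),
        empty_fraction=1.0 - len(non_empty) / len(corpus),
    )
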