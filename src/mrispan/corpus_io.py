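"""Annotated report corpora: BRAT standoff I/O, normalization, BIOES tags.

Internal coordinates are 0-based half-open ``[start, end)`` throughout.
Gold spans are required to be non-overlapping; overlap is rejected loudly
rather than silently resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: the two gold entity labels
DWI_HIGH = "DWI_HIGH"
OTHER_PART = "OTHER_PART"
#: label-agnostic mention label used by the stage-1 tagger
PART = "PART"

GOLD_LABELS = frozenset({DWI_HIGH, OTHER_PART})

#: characters removed by normalization.  The full-width space (U+3000) is
#: ubiquitous in CJK clinical text and removed by default; pass a narrower
#: set to :func:`normalize_text` to disable that.
DEFAULT_WHITESPACE = frozenset({" ", "\t", "\r", "\n", "　"})


class CorpusError(ValueError):
    """Base class for corpus-layer failures."""


class AnnotationDestroyedError(CorpusError):
    """An annotation spanned only characters removed by normalization."""


class BratFormatError(CorpusError):
    """A .ann entry does not parse or disagrees with the text file."""


class OverlapError(CorpusError):
    """Overlapping spans cannot be represented in BIOES."""


@dataclass(frozen=True)
class SpanAnnotation:
    """A labelled character span, the unit of gold and predicted output."""

    doc_id: str
    start: int
    end: int
    label: str
    surface: str

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise CorpusError(
                f"invalid span [{self.start}, {self.end}) in {self.doc_id!r}")


@dataclass
class ReportDocument:
    """One examination-description text with its span annotations."""

    doc_id: str
    text: str
    annotations: list[SpanAnnotation] = field(default_factory=list)

    def __post_init__(self):
        self.annotations = sorted(self.annotations, key=lambda a: (a.start, a.end))
        self.validate()

    def validate(self) -> None:
        prev_end = -1
        for ann in self.annotations:
            if ann.end > len(self.text):
                raise CorpusError(
                    f"annotation [{ann.start}, {ann.end}) outside text of "
                    f"length {len(self.text)} in {self.doc_id!r}")
            if ann.start < prev_end:
                raise OverlapError(
                    f"overlapping annotations in {self.doc_id!r} at {ann.start}")
            if self.text[ann.start:ann.end] != ann.surface:
                raise CorpusError(
                    f"surface mismatch in {self.doc_id!r}: "
                    f"{self.text[ann.start:ann.end]!r} != {ann.surface!r}")
            prev_end = ann.end

    def __eq__(self, other):
        if not isinstance(other, ReportDocument):
            return NotImplemented
        return (self.doc_id == other.doc_id and self.text == other.text
                and self.annotations == other.annotations)


@dataclass
class TagSequence:
    """Per-character BIOES tags: ``O`` or ``{B,I,E,S}-<label>``."""

    doc_id: str
    tags: list[str]


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _fold_case(ch: str) -> str:
    # only ASCII upper-case letters are folded; CJK text is untouched
    return ch.lower() if "A" <= ch <= "Z" else ch


def normalize_text(
    raw: str,
    annotations: Sequence[SpanAnnotation] = (),
    whitespace: frozenset[str] = DEFAULT_WHITESPACE,
) -> tuple[str, list[SpanAnnotation]]:
    """Remove whitespace/line breaks, lower-case ASCII, remap offsets.

    Returns the normalized text and annotations whose offsets address it.
    Raises :class:`AnnotationDestroyedError` if a span consists solely of
    removed characters.
    """
    kept: list[str] = []
    # old index -> new index of the character, or -1 if removed
    index_map = np.full(len(raw) + 1, -1, dtype=np.int64)
    for i, ch in enumerate(raw):
        if ch in whitespace:
            continue
        index_map[i] = len(kept)
        kept.append(_fold_case(ch))
    index_map[len(raw)] = len(kept)
    text = "".join(kept)

    remapped: list[SpanAnnotation] = []
    for ann in annotations:
        if ann.end > len(raw):
            raise CorpusError(
                f"annotation [{ann.start}, {ann.end}) outside raw text")
        inside = [index_map[i] for i in range(ann.start, ann.end) if index_map[i] >= 0]
        if not inside:
            raise AnnotationDestroyedError(
                f"annotation at [{ann.start}, {ann.end}) in {ann.doc_id!r} "
                "destroyed by normalization")
        new_start, new_end = inside[0], inside[-1] + 1
        remapped.append(replace(ann, start=int(new_start), end=int(new_end),
                                surface=text[new_start:new_end]))
    return text, remapped


def normalize_document(doc: ReportDocument,
                       whitespace: frozenset[str] = DEFAULT_WHITESPACE) -> ReportDocument:
    text, anns = normalize_text(doc.text, doc.annotations, whitespace)
    return ReportDocument(doc.doc_id, text, anns)


# ---------------------------------------------------------------------------
# BRAT standoff
# ---------------------------------------------------------------------------

def read_brat(text_path, ann_path,
              allowed_labels: frozenset[str] = GOLD_LABELS) -> ReportDocument:
    """Read a ``.txt`` + ``.ann`` pair into a :class:`ReportDocument`.

    Only T (text-bound) entries are interpreted; other entry types are
    skipped with a warning.  Surfaces are verified against the text.
    """
    text_path, ann_path = Path(text_path), Path(ann_path)
    text = text_path.read_text(encoding="utf-8")
    doc_id = text_path.stem
    annotations: list[SpanAnnotation] = []
    for lineno, line in enumerate(ann_path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        if not line.startswith("T"):
            logger.warning("%s:%d: ignoring non-T entry %r", ann_path, lineno,
                           line.split("\t", 1)[0])
            continue
        try:
            _tid, meta, surface = line.split("\t")
            label, start_s, end_s = meta.split(" ")
            start, end = int(start_s), int(end_s)
        except ValueError as err:
            raise BratFormatError(f"{ann_path}:{lineno}: unparsable T entry") from err
        if label not in allowed_labels:
            raise BratFormatError(
                f"{ann_path}:{lineno}: unknown entity label {label!r}")
        if text[start:end] != surface:
            raise BratFormatError(
                f"{ann_path}:{lineno}: offset/text disagreement: "
                f"text slice {text[start:end]!r} != surface {surface!r}")
        annotations.append(SpanAnnotation(doc_id, start, end, label, surface))
    return ReportDocument(doc_id, text, annotations)


def write_brat(doc: ReportDocument, text_path, ann_path) -> None:
    """Write a document as a BRAT ``.txt`` + ``.ann`` pair."""
    Path(text_path).write_text(doc.text, encoding="utf-8")
    lines = []
    for i, ann in enumerate(doc.annotations, 1):
        lines.append(f"T{i}\t{ann.label} {ann.start} {ann.end}\t{ann.surface}")
    Path(ann_path).write_text("\n".join(lines) + ("\n" if lines else ""),
                              encoding="utf-8")


def write_corpus(docs: Iterable[ReportDocument], directory,
                 manifest_name: str = "corpus.manifest") -> Path:
    """Write a corpus as BRAT pairs plus a plain-text manifest of stems."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stems = []
    for doc in docs:
        write_brat(doc, directory / f"{doc.doc_id}.txt", directory / f"{doc.doc_id}.ann")
        stems.append(doc.doc_id)
    manifest = directory / manifest_name
    manifest.write_text("\n".join(stems) + ("\n" if stems else ""), encoding="utf-8")
    return manifest


def read_corpus(directory, manifest_name: str = "corpus.manifest",
                allowed_labels: frozenset[str] = GOLD_LABELS) -> list[ReportDocument]:
    directory = Path(directory)
    manifest = directory / manifest_name
    if manifest.exists():
        stems = [s for s in manifest.read_text(encoding="utf-8").splitlines() if s]
    else:
        stems = sorted(p.stem for p in directory.glob("*.txt"))
    return [read_brat(directory / f"{s}.txt", directory / f"{s}.ann", allowed_labels)
            for s in stems]


# ---------------------------------------------------------------------------
# BIOES conversion
# ---------------------------------------------------------------------------

def to_bioes(doc: ReportDocument) -> TagSequence:
    """Encode non-overlapping spans as BIOES tags, one per character."""
    tags = ["O"] * len(doc.text)
    for ann in doc.annotations:
        for pos in range(ann.start, ann.end):
            if tags[pos] != "O":
                raise OverlapError(
                    f"overlap at position {pos} in {doc.doc_id!r}: "
                    "not representable in BIOES")
        length = ann.end - ann.start
        if length == 1:
            tags[ann.start] = f"S-{ann.label}"
        else:
            tags[ann.start] = f"B-{ann.label}"
            for pos in range(ann.start + 1, ann.end - 1):
                tags[pos] = f"I-{ann.label}"
            tags[ann.end - 1] = f"E-{ann.label}"
    return TagSequence(doc.doc_id, tags)


def bioes_spans(tags: Sequence[str]) -> tuple[list[tuple[int, int, str]], int]:
    """Decode BIOES tags into ``(start, end, label)`` spans.

    Tolerates illegal transitions: maximal legal segments become spans and
    every illegal fragment (dangling I, unclosed B, mismatched label, ...)
    is dropped.  Returns ``(spans, n_dropped)``.
    """
    spans: list[tuple[int, int, str]] = []
    dropped = 0
    open_start: int | None = None
    open_label: str | None = None

    def drop_open():
        nonlocal dropped, open_start, open_label
        if open_start is not None:
            dropped += 1
            open_start = open_label = None

    for i, tag in enumerate(tags):
        if tag == "O":
            drop_open()
            continue
        prefix, _, label = tag.partition("-")
        if prefix == "S":
            drop_open()
            spans.append((i, i + 1, label))
        elif prefix == "B":
            drop_open()
            open_start, open_label = i, label
        elif prefix == "I":
            if open_start is None or label != open_label:
                drop_open()
                dropped += 1
        elif prefix == "E":
            if open_start is not None and label == open_label:
                spans.append((open_start, i + 1, label))
                open_start = open_label = None
            else:
                drop_open()
                dropped += 1
        else:
            raise CorpusError(f"unknown tag {tag!r} at position {i}")
    drop_open()
    return spans, dropped


def from_bioes(tag_seq: TagSequence, text: str) -> ReportDocument:
    """Inverse of :func:`to_bioes`; illegal fragments are dropped."""
    if len(tag_seq.tags) != len(text):
        raise CorpusError(
            f"tag/text length mismatch: {len(tag_seq.tags)} != {len(text)}")
    spans, dropped = bioes_spans(tag_seq.tags)
    if dropped:
        logger.warning("%s: dropped %d illegal BIOES fragment(s)",
                       tag_seq.doc_id, dropped)
    annotations = [
        SpanAnnotation(tag_seq.doc_id, s, e, label, text[s:e])
        for s, e, label in spans
    ]
    return ReportDocument(tag_seq.doc_id, text, annotations)


# ---------------------------------------------------------------------------
# corpus splitting
# ---------------------------------------------------------------------------

def split_corpus(docs: Sequence[ReportDocument], ratio: float = 0.8,
                 seed: int = 0) -> tuple[list[ReportDocument], list[ReportDocument]]:
    """Deterministic shuffled split; ``|train| = round(ratio * N)``."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    n = len(docs)
    if n < 2:
        raise ValueError("need at least 2 documents to split")
    order = np.random.default_rng(seed).permutation(n)
    n_train = int(round(ratio * n))
    train = [docs[i] for i in order[:n_train]]
    test = [docs[i] for i in order[n_train:]]
    return train, test
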