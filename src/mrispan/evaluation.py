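"""Strict span-triple matching metrics and multi-seed error-bar reports.

A prediction is correct only when document id, start and end all equal a
gold triple's exactly.  Triples use the internal 0-based half-open
convention; converters to/from the 1-based inclusive convention are
provided for interoperability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, NamedTuple, Sequence

from .corpus_io import DWI_HIGH, ReportDocument, SpanAnnotation

logger = logging.getLogger(__name__)


class SpanTriple(NamedTuple):
    """``<d, pos_start, pos_end>`` with 0-based half-open positions."""

    d: str
    pos_start: int
    pos_end: int


def triple_from_annotation(ann: SpanAnnotation) -> SpanTriple:
    return SpanTriple(ann.doc_id, ann.start, ann.end)


def triples_from_documents(docs: Iterable[ReportDocument],
                           label: str = DWI_HIGH) -> list[SpanTriple]:
    """Collect the gold triples carrying ``label`` from a corpus."""
    return [triple_from_annotation(a) for doc in docs
            for a in doc.annotations if a.label == label]


def to_one_based_inclusive(triple: SpanTriple) -> SpanTriple:
    """Convert to the 1-based inclusive convention used in prose examples."""
    return SpanTriple(triple.d, triple.pos_start + 1, triple.pos_end)


def from_one_based_inclusive(triple: SpanTriple) -> SpanTriple:
    return SpanTriple(triple.d, triple.pos_start - 1, triple.pos_end)


@dataclass(frozen=True)
class MetricsReport:
    """Precision/recall/F1 with the underlying counts.

    ``both_empty`` flags the degenerate convention P = R = F1 = 1 used when
    neither predictions nor gold exist.
    """

    precision: float
    recall: float
    f1: float
    n_pred: int
    n_gold: int
    n_matched: int
    both_empty: bool = False

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n_pred": self.n_pred,
            "n_gold": self.n_gold,
            "n_matched": self.n_matched,
            "both_empty": self.both_empty,
        }


def strict_match_metrics(pred: Sequence[SpanTriple],
                         gold: Sequence[SpanTriple]) -> MetricsReport:
    """P = |Pre ∩ Gol| / |Pre|, R = |Pre ∩ Gol| / |Gol|, F1 = 2PR/(P+R).

    Duplicates are removed before counting.  Conventions for empty sets:
    an empty side yields 0 for its ratio, both sides empty yields perfect
    scores with ``both_empty`` set, and F1 is 0 when P + R == 0.
    """
    pred_set = {SpanTriple(*t) for t in pred}
    gold_set = {SpanTriple(*t) for t in gold}
    if not pred_set and not gold_set:
        return MetricsReport(1.0, 1.0, 1.0, 0, 0, 0, both_empty=True)
    matched = len(pred_set & gold_set)
    precision = matched / len(pred_set) if pred_set else 0.0
    recall = matched / len(gold_set) if gold_set else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return MetricsReport(precision, recall, f1,
                         len(pred_set), len(gold_set), matched)


@dataclass
class ErrorBarReport:
    """Per-seed metrics plus mean and sample standard deviation of F1."""

    runs: list[tuple[int, MetricsReport]]
    failures: list[tuple[int, str]]
    f1_mean: float
    f1_std: float

    def as_dict(self) -> dict:
        return {
            "runs": [{"seed": s, **m.as_dict()} for s, m in self.runs],
            "failures": [{"seed": s, "error": e} for s, e in self.failures],
            "f1_mean": self.f1_mean,
            "f1_std": self.f1_std,
        }


def multi_seed_eval(
    run_fn: Callable[[int], Sequence[SpanTriple]],
    eval_docs: Sequence[ReportDocument],
    seeds: Sequence[int],
    label: str = DWI_HIGH,
) -> ErrorBarReport:
    """Train/evaluate once per seed and summarise F1 as mean ± sample s.d.

    ``run_fn(seed)`` must return predicted triples for ``eval_docs``.  A
    seed whose run raises is recorded as a failure and excluded with a
    warning rather than aborting the sweep.
    """
    if len(seeds) < 2:
        raise ValueError("error bars require at least 2 seeds")
    gold = triples_from_documents(eval_docs, label=label)
    runs: list[tuple[int, MetricsReport]] = []
    failures: list[tuple[int, str]] = []
    for seed in seeds:
        try:
            pred = run_fn(seed)
        except Exception as err:  # noqa: BLE001 - failures are data here
            logger.warning("seed %d run failed: %s", seed, err)
            failures.append((seed, str(err)))
            continue
        runs.append((seed, strict_match_metrics(pred, gold)))
    f1s = [m.f1 for _, m in runs]
    mean = sum(f1s) / len(f1s) if f1s else math.nan
    if len(f1s) >= 2:
        std = math.sqrt(sum((x - mean) ** 2 for x in f1s) / (len(f1s) - 1))
    else:
        std = math.nan
    return ErrorBarReport(runs, failures, mean, std)
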