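"""Shared training plumbing: hyperparameter presets, batching, safeguards."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .encoder import PAD_ID


class TrainingDivergedError(RuntimeError):
    """Raised when a training step produces a non-finite loss."""


@dataclass(frozen=True)
class TrainingConfig:
    """Optimiser settings; the defaults are the published ones for the
    attention-based models (learning rate 3e-5, batch 32, 5 epochs, Adam)."""

    learning_rate: float = 3e-5
    batch_size: int = 32
    epochs: int = 5
    optimizer: str = "adam"
    grad_clip: float = 5.0
    lr_schedule: str = "constant"   # or "warmup_linear"
    warmup_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is supported")
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if self.lr_schedule not in ("constant", "warmup_linear"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")

    def lr_at(self, step: int, total_steps: int) -> float:
        """Learning rate for a 0-based optimiser step."""
        if self.lr_schedule == "constant":
            return self.learning_rate
        warmup = max(int(self.warmup_fraction * total_steps), 1)
        if step < warmup:
            return self.learning_rate * (step + 1) / warmup
        frac = (step - warmup) / max(total_steps - warmup, 1)
        return self.learning_rate * max(1.0 - 0.9 * frac, 0.1)


#: published per-model presets (character length 400 lives in EncoderConfig)
PRESETS: dict[str, TrainingConfig] = {
    "mrc_fet": TrainingConfig(learning_rate=3e-5, batch_size=32, epochs=5),
    "bert_bilstm_crf": TrainingConfig(learning_rate=3e-5, batch_size=32, epochs=5),
    "bilstm_fet": TrainingConfig(learning_rate=1e-3, batch_size=256, epochs=15),
    "bert_fet": TrainingConfig(learning_rate=3e-5, batch_size=32, epochs=5),
}


def pad_batch(sequences: Sequence[Sequence[int]]) -> tuple[np.ndarray, np.ndarray]:
    """Right-pad integer sequences with PAD; returns (ids, lengths)."""
    lengths = np.array([len(s) for s in sequences], dtype=np.int64)
    ids = np.full((len(sequences), int(lengths.max())), PAD_ID, dtype=np.int64)
    for i, seq in enumerate(sequences):
        ids[i, :len(seq)] = seq
    return ids, lengths


def epoch_batches(n_items: int, batch_size: int,
                  rng: np.random.Generator) -> Iterator[np.ndarray]:
    """Shuffled index batches for one epoch."""
    order = rng.permutation(n_items)
    for lo in range(0, n_items, batch_size):
        yield order[lo:lo + batch_size]


def bucketed_batches(lengths: Sequence[int], batch_size: int,
                     rng: np.random.Generator) -> Iterator[np.ndarray]:
    """Length-bucketed index batches, visited in shuffled order.

    Grouping similar lengths keeps padding (and the quadratic attention
    cost on it) low; shuffling the batch order keeps optimisation
    stochastic while staying deterministic for a fixed generator state.
    """
    order = np.argsort(np.asarray(lengths), kind="stable")
    batches = [order[lo:lo + batch_size]
               for lo in range(0, len(order), batch_size)]
    for i in rng.permutation(len(batches)):
        yield batches[i]


def check_finite(loss_value: float, context: str) -> None:
    if not math.isfinite(loss_value):
        raise TrainingDivergedError(
            f"non-finite loss ({loss_value}) during {context}; "
            "reduce the learning rate or inspect the data")
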