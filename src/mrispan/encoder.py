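"""Character vocabulary and pluggable contextual encoders.

The encoder maps a character-id sequence to an n x d matrix of
contextual representations consumed by the span head and taggers.  Two
interchangeable variants sit behind the same contract: a small trainable
self-attention encoder and a bidirectional recurrent (GRU) encoder.
Tokenization is strictly per character; there is no word segmentation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np

from . import nn
from .corpus_io import ReportDocument

PAD_ID, UNK_ID, CLS_ID, SEP_ID = 0, 1, 2, 3
N_RESERVED = 4
_RESERVED_NAMES = ("<pad>", "<unk>", "<cls>", "<sep>")

#: room left for CLS + question + SEP ahead of the report characters
MAX_QUESTION_OVERHEAD = 64

ENCODER_KINDS = ("self_attention", "recurrent_bidirectional")


@dataclass(frozen=True)
class Vocabulary:
    """Dense character-to-id map with four reserved ids at the bottom."""

    char_to_id: dict[str, int]

    @property
    def size(self) -> int:
        return N_RESERVED + len(self.char_to_id)

    def id_of(self, char: str) -> int:
        return self.char_to_id.get(char, UNK_ID)

    def encode(self, text: str) -> list[int]:
        return [self.id_of(ch) for ch in text]

    def save(self, path) -> None:
        lines = [f"{name}\t{i}" for i, name in enumerate(_RESERVED_NAMES)]
        for char, idx in sorted(self.char_to_id.items(), key=lambda kv: kv[1]):
            lines.append(f"{char}\t{idx}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path) -> "Vocabulary":
        mapping: dict[str, int] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line:
                continue
            char, idx = line.rsplit("\t", 1)
            if char in _RESERVED_NAMES:
                continue
            mapping[char] = int(idx)
        return cls(mapping)


def build_vocab(corpus: Iterable[Union[ReportDocument, str]],
                extra_texts: Iterable[str] = ()) -> Vocabulary:
    """Build a vocabulary covering every character seen in the corpus.

    Characters are assigned ids in sorted order, so the same corpus always
    yields the same map.  Unseen characters resolve to UNK at lookup time.
    """
    chars: set[str] = set()
    n = 0
    for item in corpus:
        text = item.text if isinstance(item, ReportDocument) else item
        chars.update(text)
        n += 1
    if n == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    for text in extra_texts:
        chars.update(text)
    return Vocabulary({ch: N_RESERVED + i for i, ch in enumerate(sorted(chars))})


@dataclass(frozen=True)
class EncoderConfig:
    kind: str = "self_attention"
    hidden_dim: int = 64
    n_layers: int = 2
    n_heads: int = 2
    ffn_dim: int | None = None
    max_length: int = 400
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ENCODER_KINDS:
            raise ValueError(f"unknown encoder kind {self.kind!r}")
        if self.hidden_dim <= 0 or self.max_length <= 0 or self.n_layers <= 0:
            raise ValueError("hidden_dim, n_layers and max_length must be positive")

    @property
    def resolved_ffn_dim(self) -> int:
        return self.ffn_dim if self.ffn_dim is not None else 4 * self.hidden_dim


@dataclass
class EncodedMatrix:
    """The n x d contextual representation of the report characters."""

    values: np.ndarray

    def __post_init__(self):
        if self.values.ndim != 2:
            raise ValueError("EncodedMatrix must be 2-d")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("EncodedMatrix contains non-finite entries")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]


class CharEncoder(nn.Module):
    """Embedding + local window stem + attention or BiGRU stack.

    The stem mixes each character embedding with its +/-2 neighbourhood
    (a kernel-5 convolution), giving the model n-gram boundary features
    without having to learn them through attention from scratch.
    """

    STEM_WINDOW = 2

    def __init__(self, vocab_size: int, config: EncoderConfig):
        super().__init__()
        self.config = config
        self.vocab_size = vocab_size
        rng = np.random.default_rng(config.seed)
        d = config.hidden_dim
        self.embed = nn.Embedding(vocab_size, d, rng)
        self.max_positions = config.max_length + MAX_QUESTION_OVERHEAD
        self.pos_embed = nn.Embedding(self.max_positions, d, rng)
        width = 2 * self.STEM_WINDOW + 1
        self.stem = nn.Linear(width * d, d, rng)
        self.stem_norm = nn.LayerNorm(d)
        if config.kind == "self_attention":
            self.layers = [
                nn.TransformerLayer(d, config.n_heads, config.resolved_ffn_dim,
                                    rng, config.dropout)
                for _ in range(config.n_layers)
            ]
        else:
            self.layers = [nn.BiGRULayer(d, d, rng) for _ in range(config.n_layers)]
        self.drop = nn.Dropout(config.dropout, rng)

    def _local_stem(self, x: nn.Tensor, mask: np.ndarray) -> nn.Tensor:
        B, L, d = x.data.shape
        m = nn.Tensor(mask.astype(np.float32)[:, :, None])
        x = x * m  # zero out padding so windows do not leak it
        shifted = []
        for offset in range(-self.STEM_WINDOW, self.STEM_WINDOW + 1):
            idx = np.arange(L) + offset
            valid = (idx >= 0) & (idx < L)
            gathered = x[:, np.clip(idx, 0, L - 1), :]
            gathered = gathered * nn.Tensor(valid.astype(np.float32)[None, :, None])
            shifted.append(gathered)
        return self.stem_norm(self.stem(nn.concat(shifted, axis=-1)))

    def __call__(self, ids: np.ndarray, lengths: np.ndarray) -> nn.Tensor:
        """Encode a padded id batch ``(B, L)`` into ``(B, L, d)``."""
        ids = np.asarray(ids)
        if ids.ndim != 2:
            raise ValueError("ids must be a (batch, length) array")
        B, L = ids.shape
        if L > self.max_positions:
            raise ValueError(f"sequence length {L} exceeds {self.max_positions}")
        if ids.max(initial=0) >= self.vocab_size or ids.min(initial=0) < 0:
            raise ValueError("token id out of vocabulary range")
        mask = (np.arange(L)[None, :] < np.asarray(lengths)[:, None])
        x = self._local_stem(self.embed(ids), mask) + self.pos_embed(np.arange(L))
        x = self.drop(x)
        if self.config.kind == "self_attention":
            bias = np.where(mask, 0.0, -1e9).astype(np.float32)[:, None, None, :]
            for layer in self.layers:
                x = layer(x, bias)
        else:
            for layer in self.layers:
                x = layer(x, mask.astype(np.float32))
        return x


def encode_sequence(token_ids, encoder: CharEncoder,
                    report_offset: int = 0,
                    report_length: int | None = None) -> EncodedMatrix:
    """Run the encoder on one sequence and return the report-row matrix.

    Rows covering CLS/question/SEP positions (everything before
    ``report_offset``) are computed but excluded, so the result has one
    row per report character.  Always runs in evaluation mode.
    """
    ids = np.asarray(token_ids, dtype=np.int64)[None, :]
    was_training = encoder.training
    encoder.eval()
    try:
        out = encoder(ids, np.array([ids.shape[1]]))
    finally:
        encoder.train(was_training)
    values = out.data[0]
    if report_length is None:
        report_length = values.shape[0] - report_offset
    return EncodedMatrix(values[report_offset:report_offset + report_length])


# ---------------------------------------------------------------------------
# checkpointing helpers shared by the model wrappers
# ---------------------------------------------------------------------------

def save_weights(module: nn.Module, path) -> None:
    arrays = {name: p.data for name, p in module.named_parameters()}
    np.savez(path, **arrays)


def load_weights(module: nn.Module, path) -> None:
    with np.load(path) as bundle:
        for name, p in module.named_parameters():
            p.data = bundle[name].astype(p.data.dtype)


def save_encoder_config(config: EncoderConfig, path) -> None:
    Path(path).write_text(json.dumps(asdict(config), indent=2), encoding="utf-8")


def load_encoder_config(path) -> EncoderConfig:
    return EncoderConfig(**json.loads(Path(path).read_text(encoding="utf-8")))
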