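"""Minimal reverse-mode automatic differentiation over NumPy arrays.

This module implements exactly the primitives needed by the character
encoders, the span head and the linear-chain CRF used elsewhere in the
package: broadcast arithmetic, (batched) matmul, gather, softmax /
log-softmax / logsumexp, layer normalisation, dropout, a multi-head
self-attention block, a bidirectional GRU and the Adam optimizer.

Gradients are float arrays accumulated into ``Tensor.grad``; graphs are
built dynamically and freed after ``backward``.  Everything is CPU-only
and deterministic given the ``numpy.random.Generator`` streams handed to
the layers.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "softmax",
    "log_softmax",
    "logsumexp",
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "Dropout",
    "MultiHeadSelfAttention",
    "FeedForward",
    "TransformerLayer",
    "BiGRULayer",
    "Adam",
    "clip_grad_norm",
]


def _coerce(data) -> np.ndarray:
    if isinstance(data, np.ndarray):
        return data
    return np.asarray(data, dtype=np.float32)


class Tensor:
    """An n-d array plus the machinery to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward=None):
        self.data = _coerce(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self._parents = _parents if self.requires_grad else ()
        self._backward = _backward if self.requires_grad else None

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- autograd driver ----------------------------------------------
    def backward(self) -> None:
        """Backpropagate from this tensor (gradient seeded with ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent in node._parents:
                stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
        # break reference cycles so big graphs are collected promptly
        for node in topo:
            if node is not self:
                node._parents = ()
                node._backward = None

    # -- operators -----------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __neg__(self):
        return mul(self, -1.0)

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return div(self, other)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return take(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        count = self.data.size if axis is None else _axis_size(self.data.shape, axis)
        return tsum(self, axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, shape):
        return reshape(self, shape)

    def transpose(self, axes):
        return transpose(self, axes)

    def exp(self):
        return exp(self)

    def log(self):
        return log(self)

    def tanh(self):
        return tanh(self)

    def sigmoid(self):
        return sigmoid(self)

    def relu(self):
        return relu(self)


def _axis_size(shape, axis) -> int:
    if isinstance(axis, int):
        return shape[axis]
    size = 1
    for a in axis:
        size *= shape[a]
    return size


def _t(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def _acc(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = np.zeros_like(t.data)
    t.grad += g


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    out = Tensor(a.data + b.data, _parents=(a, b))

    def bwd():
        _acc(a, _unbroadcast(out.grad, a.data.shape))
        _acc(b, _unbroadcast(out.grad, b.data.shape))

    out._backward = bwd if out.requires_grad else None
    return out


def mul(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    out = Tensor(a.data * b.data, _parents=(a, b))

    def bwd():
        _acc(a, _unbroadcast(out.grad * b.data, a.data.shape))
        _acc(b, _unbroadcast(out.grad * a.data, b.data.shape))

    out._backward = bwd if out.requires_grad else None
    return out


def div(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    out = Tensor(a.data / b.data, _parents=(a, b))

    def bwd():
        _acc(a, _unbroadcast(out.grad / b.data, a.data.shape))
        _acc(b, _unbroadcast(-out.grad * a.data / (b.data ** 2), b.data.shape))

    out._backward = bwd if out.requires_grad else None
    return out


def matmul(a, b) -> Tensor:
    a, b = _t(a), _t(b)
    out = Tensor(a.data @ b.data, _parents=(a, b))

    def bwd():
        g = out.grad
        _acc(a, _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape))
        _acc(b, _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape))

    out._backward = bwd if out.requires_grad else None
    return out


def power(a, p: float) -> Tensor:
    a = _t(a)
    out = Tensor(a.data ** p, _parents=(a,))

    def bwd():
        _acc(a, out.grad * p * a.data ** (p - 1))

    out._backward = bwd if out.requires_grad else None
    return out


def take(a, idx) -> Tensor:
    """Index/gather; supports basic slicing and integer-array indexing."""
    a = _t(a)
    out = Tensor(a.data[idx], _parents=(a,))

    def bwd():
        g = np.zeros_like(a.data)
        np.add.at(g, idx, out.grad)
        _acc(a, g)

    out._backward = bwd if out.requires_grad else None
    return out


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _t(a)
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), _parents=(a,))

    def bwd():
        g = out.grad
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _acc(a, np.broadcast_to(g, a.data.shape))

    out._backward = bwd if out.requires_grad else None
    return out


def reshape(a, shape) -> Tensor:
    a = _t(a)
    out = Tensor(a.data.reshape(shape), _parents=(a,))

    def bwd():
        _acc(a, out.grad.reshape(a.data.shape))

    out._backward = bwd if out.requires_grad else None
    return out


def transpose(a, axes) -> Tensor:
    a = _t(a)
    out = Tensor(a.data.transpose(axes), _parents=(a,))
    inv = np.argsort(axes)

    def bwd():
        _acc(a, out.grad.transpose(inv))

    out._backward = bwd if out.requires_grad else None
    return out


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_t(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * out.grad.ndim
            sl[axis] = slice(lo, hi)
            _acc(t, out.grad[tuple(sl)])

    out._backward = bwd if out.requires_grad else None
    return out


def exp(a) -> Tensor:
    a = _t(a)
    out = Tensor(np.exp(a.data), _parents=(a,))

    def bwd():
        _acc(a, out.grad * out.data)

    out._backward = bwd if out.requires_grad else None
    return out


def log(a) -> Tensor:
    a = _t(a)
    out = Tensor(np.log(a.data), _parents=(a,))

    def bwd():
        _acc(a, out.grad / a.data)

    out._backward = bwd if out.requires_grad else None
    return out


def tanh(a) -> Tensor:
    a = _t(a)
    out = Tensor(np.tanh(a.data), _parents=(a,))

    def bwd():
        _acc(a, out.grad * (1.0 - out.data ** 2))

    out._backward = bwd if out.requires_grad else None
    return out


def sigmoid(a) -> Tensor:
    a = _t(a)
    with np.errstate(over="ignore"):
        y = 1.0 / (1.0 + np.exp(-a.data))
    out = Tensor(y, _parents=(a,))

    def bwd():
        _acc(a, out.grad * out.data * (1.0 - out.data))

    out._backward = bwd if out.requires_grad else None
    return out


def relu(a) -> Tensor:
    a = _t(a)
    out = Tensor(np.maximum(a.data, 0.0), _parents=(a,))

    def bwd():
        _acc(a, out.grad * (a.data > 0))

    out._backward = bwd if out.requires_grad else None
    return out


def softmax(a, axis: int = -1) -> Tensor:
    a = _t(a)
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    y = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(y, _parents=(a,))

    def bwd():
        g = out.grad
        _acc(a, y * (g - (g * y).sum(axis=axis, keepdims=True)))

    out._backward = bwd if out.requires_grad else None
    return out


def log_softmax(a, axis: int = -1) -> Tensor:
    a = _t(a)
    m = a.data.max(axis=axis, keepdims=True)
    shifted = a.data - m
    lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
    out = Tensor(shifted - lse, _parents=(a,))

    def bwd():
        g = out.grad
        _acc(a, g - np.exp(out.data) * g.sum(axis=axis, keepdims=True))

    out._backward = bwd if out.requires_grad else None
    return out


def logsumexp(a, axis: int = -1, keepdims: bool = False) -> Tensor:
    a = _t(a)
    m = a.data.max(axis=axis, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    lse_keep = np.log(np.exp(a.data - m).sum(axis=axis, keepdims=True)) + m
    out_data = lse_keep if keepdims else np.squeeze(lse_keep, axis=axis)
    out = Tensor(out_data, _parents=(a,))

    def bwd():
        g = out.grad
        if not keepdims:
            g = np.expand_dims(g, axis)
        _acc(a, np.exp(a.data - lse_keep) * g)

    out._backward = bwd if out.requires_grad else None
    return out


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter traversal and train/eval mode switching."""

    def __init__(self):
        self.training = True

    def _children(self) -> Iterator["Module"]:
        for value in vars(self).values():
            if isinstance(value, Module):
                yield value
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield path, value
            elif isinstance(value, Module):
                yield from value.named_parameters(path + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{path}.{i}", item

    def parameters(self) -> list[Tensor]:
        seen: set[int] = set()
        out = []
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)


def _param(array: np.ndarray) -> Tensor:
    return Tensor(array.astype(np.float32), requires_grad=True)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _param(rng.normal(0.0, d_in ** -0.5, (d_in, d_out)))
        self.bias = _param(np.zeros(d_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Embedding(Module):
    def __init__(self, n_embeddings: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = _param(rng.normal(0.0, 0.02, (n_embeddings, dim)))

    def __call__(self, ids: np.ndarray) -> Tensor:
        return take(self.weight, ids)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = _param(np.ones(dim))
        self.beta = _param(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * (var + self.eps) ** -0.5 * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; a no-op in eval mode or at p == 0."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = (self.rng.random(x.data.shape) >= self.p).astype(np.float32)
        return x * Tensor(keep / (1.0 - self.p))


class MultiHeadSelfAttention(Module):
    """Multi-head attention with a learned relative-position bias.

    The per-head bias over clipped relative offsets lets heads attend "a
    few characters ahead/behind" without first having to learn it from
    content, which matters when training small models from scratch.
    """

    MAX_REL = 64

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        if dim % n_heads:
            raise ValueError("hidden_dim must be divisible by n_heads")
        self.n_heads = n_heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.out = Linear(dim, dim, rng)
        self.drop = Dropout(dropout, rng)
        self.rel_bias = _param(np.zeros((2 * self.MAX_REL + 1, n_heads)))

    def _relative_bias(self, L: int) -> Tensor:
        offsets = np.arange(L)[None, :] - np.arange(L)[:, None]
        idx = np.clip(offsets, -self.MAX_REL, self.MAX_REL) + self.MAX_REL
        return take(self.rel_bias, idx).transpose((2, 0, 1))  # (h, L, L)

    def __call__(self, x: Tensor, bias: np.ndarray | None = None) -> Tensor:
        B, L, D = x.data.shape
        h, dh = self.n_heads, D // self.n_heads
        qkv = self.qkv(x)
        q = qkv[:, :, 0:D].reshape((B, L, h, dh)).transpose((0, 2, 1, 3))
        k = qkv[:, :, D:2 * D].reshape((B, L, h, dh)).transpose((0, 2, 1, 3))
        v = qkv[:, :, 2 * D:3 * D].reshape((B, L, h, dh)).transpose((0, 2, 1, 3))
        scores = (q @ k.transpose((0, 1, 3, 2))) * (dh ** -0.5)
        scores = scores + self._relative_bias(L).reshape((1, h, L, L))
        if bias is not None:
            scores = scores + Tensor(bias)
        attn = self.drop(softmax(scores, axis=-1))
        ctx = (attn @ v).transpose((0, 2, 1, 3)).reshape((B, L, D))
        return self.drop(self.out(ctx))


class FeedForward(Module):
    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        self.lin1 = Linear(dim, hidden, rng)
        self.lin2 = Linear(hidden, dim, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.drop(self.lin2(relu(self.lin1(x))))


class TransformerLayer(Module):
    """Post-norm transformer block (attention + position-wise FFN)."""

    def __init__(self, dim: int, n_heads: int, ffn_dim: int,
                 rng: np.random.Generator, dropout: float = 0.0):
        super().__init__()
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng, dropout)
        self.ffn = FeedForward(dim, ffn_dim, rng, dropout)
        self.ln1 = LayerNorm(dim)
        self.ln2 = LayerNorm(dim)

    def __call__(self, x: Tensor, bias: np.ndarray | None = None) -> Tensor:
        x = self.ln1(x + self.attn(x, bias))
        return self.ln2(x + self.ffn(x))


class _GRUDirection(Module):
    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator,
                 reverse: bool):
        super().__init__()
        self.h = d_hidden
        self.reverse = reverse
        self.w_rz = _param(rng.normal(0.0, d_in ** -0.5, (d_in, 2 * d_hidden)))
        self.u_rz = _param(rng.normal(0.0, d_hidden ** -0.5, (d_hidden, 2 * d_hidden)))
        self.b_rz = _param(np.zeros(2 * d_hidden))
        self.w_n = _param(rng.normal(0.0, d_in ** -0.5, (d_in, d_hidden)))
        self.u_n = _param(rng.normal(0.0, d_hidden ** -0.5, (d_hidden, d_hidden)))
        self.b_n = _param(np.zeros(d_hidden))

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        B, L, _ = x.data.shape
        xp_rz = x @ self.w_rz + self.b_rz
        xp_n = x @ self.w_n + self.b_n
        h = Tensor(np.zeros((B, self.h), dtype=np.float32))
        outs: list[Tensor | None] = [None] * L
        steps = range(L - 1, -1, -1) if self.reverse else range(L)
        for t in steps:
            gates = sigmoid(xp_rz[:, t] + h @ self.u_rz)
            r = gates[:, :self.h]
            z = gates[:, self.h:]
            n = tanh(xp_n[:, t] + r * (h @ self.u_n))
            h_new = (1.0 - z) * h + z * n
            m = mask[:, t:t + 1].astype(np.float32)
            h = h_new * Tensor(m) + h * Tensor(1.0 - m)
            outs[t] = h.reshape((B, 1, self.h))
        return concat(outs, axis=1)


class BiGRULayer(Module):
    """Bidirectional GRU; forward/backward states concatenated to d_out."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        if d_out % 2:
            raise ValueError("BiGRU output dim must be even")
        self.fwd = _GRUDirection(d_in, d_out // 2, rng, reverse=False)
        self.bwd = _GRUDirection(d_in, d_out // 2, rng, reverse=True)

    def __call__(self, x: Tensor, mask: np.ndarray) -> Tensor:
        return concat([self.fwd(x, mask), self.bwd(x, mask)], axis=-1)


# ---------------------------------------------------------------------------
# optimisation
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive-moment estimation with bias correction."""

    def __init__(self, params: Iterable[Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            m_hat = self.m[i] / bc1
            v_hat = self.v[i] / bc2
            p.data -= (self.lr * m_hat / (np.sqrt(v_hat) + self.eps)).astype(p.data.dtype)


def clip_grad_norm(params: Iterable[Tensor], max_norm: float) -> float:
    """Scale gradients in place so their global L2 norm is <= max_norm."""
    params = [p for p in params if p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad ** 2).sum()) for p in params)))
    if total > max_norm and total > 0.0:
        scale = max_norm / total
        for p in params:
            p.grad *= scale
    return total
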