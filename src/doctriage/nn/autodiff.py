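"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Only the operations the document encoders need are provided: broadcast
arithmetic, matrix products, the sigmoid/tanh/ReLU nonlinearities,
concatenation, row gathers (embedding lookup), masked max/softmax over
time, and a fused softmax cross-entropy loss.  Everything is float64 for
reproducibility on CPU.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "constant",
    "add",
    "mul",
    "matmul",
    "sigmoid",
    "tanh",
    "relu",
    "concat",
    "gather_rows",
    "column",
    "masked_max",
    "masked_softmax",
    "weighted_sum",
    "softmax_cross_entropy",
    "softmax",
    "backward",
]


class Tensor:
    """A node in the computation graph wrapping an ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward_fn: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward_fn

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=requires_grad)


def constant(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=False)


def _needs_graph(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in ts)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum gradient g down to `shape` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data
    if not _needs_graph(a, b):
        return Tensor(out_data)
    out = Tensor(out_data, parents=(a, b))

    def bw(g: np.ndarray) -> None:
        if a.requires_grad or a._parents:
            a.accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad or b._parents:
            b.accumulate(_unbroadcast(g, b.data.shape))

    out._backward = bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data
    if not _needs_graph(a, b):
        return Tensor(out_data)
    out = Tensor(out_data, parents=(a, b))

    def bw(g: np.ndarray) -> None:
        if a.requires_grad or a._parents:
            a.accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad or b._parents:
            b.accumulate(_unbroadcast(g * a.data, b.data.shape))

    out._backward = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data
    if not _needs_graph(a, b):
        return Tensor(out_data)
    out = Tensor(out_data, parents=(a, b))

    def bw(g: np.ndarray) -> None:
        if a.requires_grad or a._parents:
            a.accumulate(g @ b.data.T)
        if b.requires_grad or b._parents:
            b.accumulate(a.data.T @ g)

    out._backward = bw
    return out


def sigmoid(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    if not _needs_graph(a):
        return Tensor(s)
    out = Tensor(s, parents=(a,))

    def bw(g: np.ndarray) -> None:
        a.accumulate(g * s * (1.0 - s))

    out._backward = bw
    return out


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)
    if not _needs_graph(a):
        return Tensor(t)
    out = Tensor(t, parents=(a,))

    def bw(g: np.ndarray) -> None:
        a.accumulate(g * (1.0 - t * t))

    out._backward = bw
    return out


def relu(a: Tensor) -> Tensor:
    r = np.maximum(a.data, 0.0)
    if not _needs_graph(a):
        return Tensor(r)
    out = Tensor(r, parents=(a,))

    def bw(g: np.ndarray) -> None:
        a.accumulate(g * (a.data > 0.0))

    out._backward = bw
    return out


def concat(parts: Sequence[Tensor], axis: int = -1) -> Tensor:
    out_data = np.concatenate([p.data for p in parts], axis=axis)
    if not _needs_graph(*parts):
        return Tensor(out_data)
    out = Tensor(out_data, parents=tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]
    offsets = np.cumsum([0] + sizes)

    def bw(g: np.ndarray) -> None:
        for p, lo, hi in zip(parts, offsets[:-1], offsets[1:]):
            if p.requires_grad or p._parents:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                p.accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def gather_rows(table: Tensor, ids: np.ndarray) -> Tensor:
    """Embedding lookup: rows of `table` indexed by integer array `ids`."""
    ids = np.asarray(ids, dtype=np.int64)
    out_data = table.data[ids]
    if not _needs_graph(table):
        return Tensor(out_data)
    out = Tensor(out_data, parents=(table,))

    def bw(g: np.ndarray) -> None:
        if table.grad is None:
            table.grad = np.zeros_like(table.data)
        np.add.at(table.grad, ids, g)

    out._backward = bw
    return out


def column(a: Tensor, idx: int) -> Tensor:
    """Select column idx of a 2-D tensor, keeping it as (B, 1)."""
    out_data = a.data[:, idx : idx + 1]
    if not _needs_graph(a):
        return Tensor(out_data)
    out = Tensor(out_data, parents=(a,))

    def bw(g: np.ndarray) -> None:
        full = np.zeros_like(a.data)
        full[:, idx : idx + 1] = g
        a.accumulate(full)

    out._backward = bw
    return out


def masked_max(steps: Sequence[Tensor], mask: np.ndarray) -> Tensor:
    """Elementwise max over time of a list of (B, H) tensors.

    mask has shape (B, T) with 1.0 at valid positions; invalid positions
    cannot win the max.  Raises if any row has no valid position.
    """
    if not steps:
        raise ValueError("masked_max requires at least one step")
    mask = np.asarray(mask, dtype=np.float64)
    if not np.all(mask.sum(axis=1) > 0):
        raise ValueError("masked_max: a row has no valid position")
    stacked = np.stack([s.data for s in steps], axis=0)  # (T, B, H)
    neg = np.where(mask.T[:, :, None] > 0, 0.0, -np.inf)
    masked = stacked + neg
    argmax = masked.argmax(axis=0)  # (B, H)
    out_data = np.take_along_axis(masked, argmax[None], axis=0)[0]
    if not _needs_graph(*steps):
        return Tensor(out_data)
    out = Tensor(out_data, parents=tuple(steps))

    def bw(g: np.ndarray) -> None:
        for t, s in enumerate(steps):
            if s.requires_grad or s._parents:
                s.accumulate(g * (argmax == t))

    out._backward = bw
    return out


def masked_softmax(scores: Tensor, mask: np.ndarray) -> Tensor:
    """Softmax over the last axis of (B, T) scores; masked entries get 0."""
    mask = np.asarray(mask, dtype=np.float64)
    if not np.all(mask.sum(axis=1) > 0):
        raise ValueError("masked_softmax: a row has no valid position")
    z = np.where(mask > 0, scores.data, -np.inf)
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z) * (mask > 0)
    p = e / e.sum(axis=1, keepdims=True)
    if not _needs_graph(scores):
        return Tensor(p)
    out = Tensor(p, parents=(scores,))

    def bw(g: np.ndarray) -> None:
        dot = (g * p).sum(axis=1, keepdims=True)
        scores.accumulate(p * (g - dot))

    out._backward = bw
    return out


def weighted_sum(weights: Tensor, steps: Sequence[Tensor]) -> Tensor:
    """sum_t weights[:, t:t+1] * steps[t]; weights is (B, T)."""
    acc: Tensor | None = None
    for t, s in enumerate(steps):
        term = mul(column(weights, t), s)
        acc = term if acc is None else add(acc, term)
    assert acc is not None
    return acc


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Mean categorical cross-entropy; returns (loss, probabilities)."""
    labels = np.asarray(labels, dtype=np.int64)
    probs = softmax(logits.data)
    n = logits.data.shape[0]
    loss_val = -np.log(np.clip(probs[np.arange(n), labels], 1e-300, None)).mean()
    out = Tensor(np.asarray(loss_val), parents=(logits,))

    def bw(g: np.ndarray) -> None:
        grad = probs.copy()
        grad[np.arange(n), labels] -= 1.0
        logits.accumulate(g * grad / n)

    out._backward = bw
    return out, probs


def backward(root: Tensor) -> None:
    """Reverse-mode sweep from a scalar root."""
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    root.grad = np.ones_like(root.data)
    for node in reversed(topo):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)
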