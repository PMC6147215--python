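"""Recurrent, convolutional and pooling building blocks.

All sequence operations take a list of (B, input) tensors, one per time
step, plus a (B, T) validity mask.  Recurrent states are carried through
masked positions unchanged and pooling ignores them, so appending padded
positions never changes an output (length invariance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "LSTMParams",
    "ConvParams",
    "AttentionParams",
    "lstm_step",
    "lstm_sequence",
    "conv_layer",
    "max_pool_time",
    "attention_pool",
    "affine",
    "init_lstm",
    "init_conv",
    "init_attention",
    "init_matrix",
]

def init_matrix(rng: np.random.Generator, *shape: int) -> Tensor:
    """Glorot-style uniform init: limit sqrt(6 / (fan_in + fan_out))."""
    fan_in, fan_out = (shape[0], shape[-1]) if len(shape) > 1 else (shape[0], shape[0])
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return ad.tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


@dataclass
class LSTMParams:
    """Gate parameters.  The output gate additionally sees the fresh cell
    state through V_o (peephole on the output gate only)."""

    W_i: Tensor; U_i: Tensor; b_i: Tensor
    W_f: Tensor; U_f: Tensor; b_f: Tensor
    W_c: Tensor; U_c: Tensor; b_c: Tensor
    W_o: Tensor; U_o: Tensor; V_o: Tensor; b_o: Tensor
    hidden: int

    def named(self, prefix: str) -> dict[str, Tensor]:
        return {
            f"{prefix}.{k}": getattr(self, k)
            for k in ("W_i", "U_i", "b_i", "W_f", "U_f", "b_f",
                      "W_c", "U_c", "b_c", "W_o", "U_o", "V_o", "b_o")
        }


def init_lstm(rng: np.random.Generator, input_dim: int, hidden: int) -> LSTMParams:
    def W() -> Tensor:
        return init_matrix(rng, input_dim, hidden)

    def U() -> Tensor:
        return init_matrix(rng, hidden, hidden)

    def b() -> Tensor:
        return ad.tensor(np.zeros(hidden), requires_grad=True)

    return LSTMParams(
        W_i=W(), U_i=U(), b_i=b(),
        W_f=W(), U_f=U(), b_f=b(),
        W_c=W(), U_c=U(), b_c=b(),
        W_o=W(), U_o=U(), V_o=init_matrix(rng, hidden, hidden), b_o=b(),
        hidden=hidden,
    )


def lstm_step(x: Tensor, h_prev: Tensor, c_prev: Tensor, p: LSTMParams) -> tuple[Tensor, Tensor]:
    """One LSTM cell update producing (h_t, c_t)."""
    if x.shape[-1] != p.W_i.shape[0]:
        raise ValueError(f"input width {x.shape[-1]} != expected {p.W_i.shape[0]}")
    i = ad.sigmoid(ad.add(ad.add(ad.matmul(x, p.W_i), ad.matmul(h_prev, p.U_i)), p.b_i))
    f = ad.sigmoid(ad.add(ad.add(ad.matmul(x, p.W_f), ad.matmul(h_prev, p.U_f)), p.b_f))
    g = ad.tanh(ad.add(ad.add(ad.matmul(x, p.W_c), ad.matmul(h_prev, p.U_c)), p.b_c))
    c = ad.add(ad.mul(f, c_prev), ad.mul(i, g))
    o = ad.sigmoid(
        ad.add(
            ad.add(ad.add(ad.matmul(x, p.W_o), ad.matmul(h_prev, p.U_o)), ad.matmul(c, p.V_o)),
            p.b_o,
        )
    )
    h = ad.mul(o, ad.tanh(c))
    return h, c


def lstm_sequence(
    xs: list[Tensor],
    mask: np.ndarray,
    p: LSTMParams,
    reverse: bool = False,
) -> list[Tensor]:
    """Run an LSTM over a masked sequence; returns hidden states aligned
    with the input order.  States carry through masked positions."""
    if not xs:
        raise ValueError("empty sequence")
    batch = xs[0].shape[0]
    h = ad.constant(np.zeros((batch, p.hidden)))
    c = ad.constant(np.zeros((batch, p.hidden)))
    order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
    out: dict[int, Tensor] = {}
    for t in order:
        h_new, c_new = lstm_step(xs[t], h, c, p)
        m = ad.constant(mask[:, t : t + 1])
        keep = ad.constant(1.0 - mask[:, t : t + 1])
        h = ad.add(ad.mul(m, h_new), ad.mul(keep, h))
        c = ad.add(ad.mul(m, c_new), ad.mul(keep, c))
        out[t] = h
    return [out[t] for t in range(len(xs))]


@dataclass
class ConvParams:
    W: Tensor  # (k * input_dim, filters), shared across windows
    b: Tensor  # (filters,)
    k: int

    def named(self, prefix: str) -> dict[str, Tensor]:
        return {f"{prefix}.W": self.W, f"{prefix}.b": self.b}


def init_conv(rng: np.random.Generator, input_dim: int, filters: int, k: int = 3) -> ConvParams:
    return ConvParams(
        W=init_matrix(rng, k * input_dim, filters),
        b=ad.tensor(np.zeros(filters), requires_grad=True),
        k=k,
    )


def conv_layer(xs: list[Tensor], p: ConvParams) -> list[Tensor]:
    """Same-length 1-D convolution: zero-pad (k-1) positions split left
    and right, then ReLU(W @ window + b) at each of the n windows."""
    if not xs:
        raise ValueError("empty sequence")
    batch, dim = xs[0].shape
    left = (p.k - 1) // 2
    right = p.k - 1 - left
    zero = ad.constant(np.zeros((batch, dim)))
    padded = [zero] * left + list(xs) + [zero] * right
    out: list[Tensor] = []
    for t in range(len(xs)):
        window = ad.concat(padded[t : t + p.k], axis=1)
        out.append(ad.relu(ad.add(ad.matmul(window, p.W), p.b)))
    return out


def mask_steps(steps: list[Tensor], mask: np.ndarray) -> list[Tensor]:
    """Zero every invalid position so downstream windows see the same
    zeros a conv layer's own boundary padding would supply."""
    return [ad.mul(s, ad.constant(mask[:, t : t + 1])) for t, s in enumerate(steps)]


def max_pool_time(steps: list[Tensor], mask: np.ndarray) -> Tensor:
    """Elementwise maximum over valid time steps."""
    return ad.masked_max(steps, mask)


@dataclass
class AttentionParams:
    W: Tensor  # (hidden, 1): projects a state to a scalar score
    b: Tensor  # (1,)

    def named(self, prefix: str) -> dict[str, Tensor]:
        return {f"{prefix}.W": self.W, f"{prefix}.b": self.b}


def init_attention(rng: np.random.Generator, hidden: int) -> AttentionParams:
    return AttentionParams(W=init_matrix(rng, hidden, 1), b=ad.tensor(np.zeros(1), requires_grad=True))


def attention_pool(
    steps: list[Tensor], mask: np.ndarray, p: AttentionParams
) -> tuple[Tensor, np.ndarray]:
    """Scalar-score attention: u_t = tanh(W h_t + b), alpha = softmax(u),
    v = sum_t alpha_t h_t.  Returns (v, alpha)."""
    scores = ad.concat(
        [ad.tanh(ad.add(ad.matmul(h, p.W), p.b)) for h in steps], axis=1
    )  # (B, T)
    alpha = ad.masked_softmax(scores, mask)
    v = ad.weighted_sum(alpha, steps)
    return v, alpha.data


def affine(x: Tensor, W: Tensor, b: Tensor) -> Tensor:
    return ad.add(ad.matmul(x, W), b)
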