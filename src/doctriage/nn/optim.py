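"""RMSprop and Adadelta with global-norm gradient clipping."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["RMSprop", "Adadelta", "clip_gradients"]


def clip_gradients(params: dict[str, Tensor], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most max_norm."""
    total = 0.0
    for t in params.values():
        if t.grad is not None:
            total += float((t.grad**2).sum())
    norm = total**0.5
    if max_norm > 0 and norm > max_norm:
        scale = max_norm / norm
        for t in params.values():
            if t.grad is not None:
                t.grad *= scale
    return norm


class RMSprop:
    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3, rho: float = 0.9, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.sq: dict[str, np.ndarray] = {k: np.zeros_like(t.data) for k, t in params.items()}

    def step(self) -> None:
        for k, t in self.params.items():
            if t.grad is None:
                continue
            self.sq[k] = self.rho * self.sq[k] + (1 - self.rho) * t.grad**2
            t.data -= self.lr * t.grad / (np.sqrt(self.sq[k]) + self.eps)

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.zero_grad()


class Adadelta:
    def __init__(self, params: dict[str, Tensor], lr: float = 1.0, rho: float = 0.95, eps: float = 1e-6):
        self.params = params
        self.lr = lr
        self.rho = rho
        self.eps = eps
        self.sq: dict[str, np.ndarray] = {k: np.zeros_like(t.data) for k, t in params.items()}
        self.dx: dict[str, np.ndarray] = {k: np.zeros_like(t.data) for k, t in params.items()}

    def step(self) -> None:
        for k, t in self.params.items():
            if t.grad is None:
                continue
            self.sq[k] = self.rho * self.sq[k] + (1 - self.rho) * t.grad**2
            update = np.sqrt(self.dx[k] + self.eps) / np.sqrt(self.sq[k] + self.eps) * t.grad
            self.dx[k] = self.rho * self.dx[k] + (1 - self.rho) * update**2
            t.data -= self.lr * update

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.zero_grad()
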