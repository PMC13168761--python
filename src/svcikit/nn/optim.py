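"""Adam optimizer with L2 weight decay and a cosine-annealed learning rate."""

from __future__ import annotations

import math

import numpy as np

from .core import Param

__all__ = ["Adam", "cosine_lr"]


class Adam:
    def __init__(
        self,
        params: list[Param],
        lr: float = 5e-5,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 1e-3,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def cosine_lr(lr0: float, epoch: int, n_epochs: int) -> float:
    """Cosine annealing from ``lr0`` at epoch 0 toward 0 at ``n_epochs``."""
    if n_epochs <= 0:
        raise ValueError("n_epochs must be positive")
    return lr0 * 0.5 * (1.0 + math.cos(math.pi * epoch / n_epochs))
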