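"""Stochastic gradient descent with classical momentum."""

from __future__ import annotations

import numpy as np

__all__ = ["SGD"]


class SGD:
    """v <- mu * v + g;  p <- p - lr * v  (optionally with weight decay)."""

    def __init__(self, params, lr: float = 0.01, momentum: float = 0.8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v
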