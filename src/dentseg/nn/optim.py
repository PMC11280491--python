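"""Optimisation: Adam and a reduce-on-plateau learning-rate scheduler."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter

__all__ = ["Adam", "ReduceLROnPlateau"]


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        b1, b2 = self.betas
        self._t += 1
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class ReduceLROnPlateau:
    """Multiply the lr by ``factor`` after ``patience`` + 1 non-improving epochs."""

    def __init__(self, optimizer: Adam, factor: float = 0.1, patience: int = 5,
                 min_lr: float = 0.0, threshold: float = 1e-8):
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.threshold = threshold
        self.best = np.inf
        self.num_bad = 0
        self.num_reductions = 0

    def step(self, metric: float) -> None:
        if metric < self.best - self.threshold:
            self.best = metric
            self.num_bad = 0
            return
        self.num_bad += 1
        if self.num_bad > self.patience:
            new_lr = max(self.optimizer.lr * self.factor, self.min_lr)
            if new_lr < self.optimizer.lr:
                self.optimizer.lr = new_lr
                self.num_reductions += 1
            self.num_bad = 0
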