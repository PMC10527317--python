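"""Optimisers for the autodiff parameter tensors."""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter

__all__ = ["Adam", "StepLR"]


class Adam:
    """Adam with the classic L2 penalty folded into the gradient.

    Defaults follow the convolutional branch's training recipe
    (betas (0.9, 0.999), eps 1e-8); learning rate and weight decay are
    per-model configuration.
    """

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bias1) / (np.sqrt(v / bias2) + self.eps)
            p.data = p.data - self.lr * update.astype(p.data.dtype, copy=False)


class StepLR:
    """Multiply the optimiser's learning rate by ``gamma`` every ``step_size`` epochs."""

    def __init__(self, optimizer: Adam, step_size: int, gamma: float = 0.1):
        self.optimizer = optimizer
        self.step_size = step_size
        self.gamma = gamma
        self.epoch = 0

    def step(self) -> None:
        self.epoch += 1
        if self.step_size > 0 and self.epoch % self.step_size == 0:
            self.optimizer.lr *= self.gamma
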