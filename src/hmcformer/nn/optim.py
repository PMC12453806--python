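"""Optimisers for the numpy NN core."""

from __future__ import annotations

import math

import numpy as np


class AdamW:
    """AdamW with decoupled weight decay (Loshchilov & Hutter)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.05):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            # decay only matrices/conv kernels, not norm/bias vectors
            if self.weight_decay and p.data.ndim > 1:
                p.data *= 1.0 - self.lr * self.weight_decay
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class CosineSchedule:
    """Cosine decay of the learning rate over a fixed number of steps."""

    def __init__(self, optimizer: AdamW, total_steps: int, min_lr: float = 1e-5):
        self.opt = optimizer
        self.base_lr = optimizer.lr
        self.total = max(1, total_steps)
        self.min_lr = min_lr
        self.step_num = 0

    def step(self):
        self.step_num += 1
        frac = min(1.0, self.step_num / self.total)
        self.opt.lr = self.min_lr + 0.5 * (self.base_lr - self.min_lr) * (
            1.0 + math.cos(math.pi * frac))
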