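"""Optimizers and learning-rate schedules for the numpy NN core."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["SGD", "Adam", "ReduceLROnPlateau", "CosineAnnealing"]


class _Optimizer:
    def __init__(self, params, lr: float):
        self.params = list(params)
        self.lr = float(lr)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class SGD(_Optimizer):
    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad


class Adam(_Optimizer):
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        super().__init__(params, lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Multiply lr by `factor` when the tracked metric stops improving.

    `mode='max'` suits validation Pearson; `patience` counts consecutive
    non-improving epochs before a reduction.
    """

    def __init__(self, optimizer, mode="max", factor=0.5, patience=3, min_lr=1e-7):
        self.optimizer = optimizer
        self.sign = 1.0 if mode == "max" else -1.0
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = -math.inf
        self.bad_epochs = 0

    def step(self, metric: float):
        if self.sign * metric > self.best:
            self.best = self.sign * metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.optimizer.lr = max(self.optimizer.lr * self.factor, self.min_lr)
                self.bad_epochs = 0


class CosineAnnealing:
    """Cyclic cosine annealing of the learning rate, restarted every `period`."""

    def __init__(self, optimizer, period=10, min_lr=1e-6):
        self.optimizer = optimizer
        self.base_lr = optimizer.lr
        self.period = period
        self.min_lr = min_lr
        self.epoch = 0

    def step(self, metric: float | None = None):
        self.epoch += 1
        phase = (self.epoch % self.period) / self.period
        self.optimizer.lr = self.min_lr + 0.5 * (self.base_lr - self.min_lr) * (
            1.0 + math.cos(math.pi * phase)
        )
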