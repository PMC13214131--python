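"""Optimisers and learning-rate schedules."""

from __future__ import annotations

import numpy as np


class AdamW:
    """Adam with decoupled weight decay.

    With ``weight_decay=0`` this is plain Adam.
    """

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            upd = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * upd


def lr_at_epoch(base_lr: float, epoch: int, total_epochs: int, schedule: str,
                step_every: int = 50, step_factor: float = 0.1) -> float:
    """Per-epoch learning rate under the named schedule.

    ``cosine``: half-cosine annealing from ``base_lr`` to 0 over ``total_epochs``.
    ``step``: multiply by ``step_factor`` after every ``step_every`` epochs.
    ``constant``: unchanged.
    """
    if schedule == "cosine":
        return base_lr * 0.5 * (1.0 + float(np.cos(np.pi * epoch / max(total_epochs, 1))))
    if schedule == "step":
        return base_lr * step_factor ** (epoch // step_every)
    if schedule == "constant":
        return base_lr
    raise ValueError(f"unknown schedule: {schedule!r}")
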