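"""Adam optimizer and the cosine-annealing learning-rate schedule."""

from __future__ import annotations

import math

import numpy as np

__all__ = ["Adam", "cosine_lr"]


def cosine_lr(step: int, total_steps: int, lr0: float, lr_min: float) -> float:
    """Cosine-annealed learning rate, no restarts.

    lr(step) = lr_min + 0.5*(lr0 - lr_min)*(1 + cos(pi * step / total_steps)),
    so lr(0) == lr0 and lr(total_steps) == lr_min, monotone nonincreasing
    in between.
    """
    if not 0 <= step <= total_steps:
        raise ValueError(f"step {step} outside [0, {total_steps}]")
    if lr_min > lr0:
        raise ValueError("lr_min must not exceed lr0")
    return lr_min + 0.5 * (lr0 - lr_min) * (1.0 + math.cos(math.pi * step / total_steps))


class Adam:
    """Adam with the standard bias-corrected first/second moments."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
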