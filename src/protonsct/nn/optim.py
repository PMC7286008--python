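"""Adam optimiser."""

from __future__ import annotations

import numpy as np

from .layers import Param

__all__ = ["Adam"]


class Adam:
    def __init__(self, params: list[Param], lr: float = 2e-4, beta1: float = 0.5,
                 beta2: float = 0.999, eps: float = 1e-8):
        if lr <= 0:
            raise ValueError("learning rate must be > 0")
        if not (0 < beta1 < 1 and 0 < beta2 < 1):
            raise ValueError("betas must be in (0, 1)")
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in params]
        self.s = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, s in zip(self.params, self.m, self.s):
            m[...] = b1 * m + (1 - b1) * p.g
            s[...] = b2 * s + (1 - b2) * p.g**2
            mhat = m / (1 - b1**self.t)
            shat = s / (1 - b2**self.t)
            p.v -= self.lr * mhat / (np.sqrt(shat) + self.eps)
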