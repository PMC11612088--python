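"""Optimizers.

AdamW: Adam moment estimation with decoupled weight decay, i.e. the decay is
applied directly to the weights rather than folded into the gradient.
"""

from __future__ import annotations

import numpy as np

__all__ = ["AdamW"]


class AdamW:
    def __init__(self, params, lr: float = 5e-5, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-5):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
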