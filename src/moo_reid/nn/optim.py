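"""First-order optimizers: Adam (default) and momentum SGD."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam", "SGD"]


class Adam:
    """Adam with bias-corrected moment estimates.

    ``beta1`` is the first-moment decay (the training protocol's "momentum"),
    default 0.9.
    """

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


class SGD:
    def __init__(self, params, lr=1e-4, momentum=0.9):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, buf in zip(self.params, self._buf):
            if p.grad is None:
                continue
            buf *= self.momentum
            buf += p.grad
            p.data -= self.lr * buf

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
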