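"""AdamW optimiser (decoupled weight decay)."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class AdamW:
    """Adam with decoupled weight decay.

    Parameters follow the common convention: ``lr`` 1e-4 by default to match
    the training protocol, betas (0.9, 0.999), eps 1e-8, weight decay 0.01.
    """

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            if self.weight_decay:
                p.data *= (1.0 - self.lr * self.weight_decay)
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
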