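"""Minimal AdamW optimizer over dicts of NumPy arrays."""

from __future__ import annotations

import numpy as np


class AdamW:
    """Adaptive moment estimation with decoupled weight decay.

    Operates in place on a dict of named parameter arrays; gradients are
    supplied as a matching dict.  Weight decay defaults to 0, in which case
    this is plain Adam.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            p = self.params[k]
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * np.square(g)
            if self.weight_decay:
                p -= self.lr * self.weight_decay * p
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
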