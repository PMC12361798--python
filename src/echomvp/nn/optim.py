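"""Gradient-descent optimisers with parameter groups.

Parameter groups carry their own learning rate, which is how the
encoder/decoder learning-rate ratio K of the segmenter is realised.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


def _as_groups(params, lr):
    if params and isinstance(params[0], dict):
        return [dict(g) for g in params]
    return [{"params": list(params), "lr": lr}]


class SGD:
    def __init__(self, params, lr: float = 0.01, momentum: float = 0.9):
        self.groups = _as_groups(params, lr)
        self.momentum = momentum
        self._velocity: dict[int, np.ndarray] = {}

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self) -> None:
        for g in self.groups:
            lr = g.get("lr", 0.01)
            for p in g["params"]:
                if p.grad is None:
                    continue
                v = self._velocity.get(id(p))
                v = self.momentum * v + p.grad if v is not None else p.grad.copy()
                self._velocity[id(p)] = v
                p.data = p.data - (lr * v).astype(p.data.dtype)


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.groups = _as_groups(params, lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}
        self._t = 0

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self) -> None:
        self._t += 1
        for g in self.groups:
            lr = g.get("lr", 1e-3)
            for p in g["params"]:
                if p.grad is None:
                    continue
                m = self._m.get(id(p), np.zeros_like(p.grad))
                v = self._v.get(id(p), np.zeros_like(p.grad))
                m = self.b1 * m + (1 - self.b1) * p.grad
                v = self.b2 * v + (1 - self.b2) * p.grad**2
                self._m[id(p)], self._v[id(p)] = m, v
                mhat = m / (1 - self.b1**self._t)
                vhat = v / (1 - self.b2**self._t)
                p.data = p.data - (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)
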