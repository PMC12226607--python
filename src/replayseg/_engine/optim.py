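"""Optimizers: SGD with momentum (segmentation nets) and AdamW (diffusion net).

Both support clipping the global gradient norm before the update, which is
what keeps the joint distillation + weighted-CE objective stable at high
learning rates.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = ["SGD", "AdamW", "clip_global_norm"]


def clip_global_norm(params: list[Tensor], max_norm: float) -> float:
    """Scale all gradients so their joint Euclidean norm is <= max_norm.

    Returns the pre-clip norm.
    """
    total = np.sqrt(sum(float((p.grad ** 2).sum())
                        for p in params if p.grad is not None))
    if total > max_norm > 0:
        scale = max_norm / (total + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad *= scale
    return total


class SGD:
    def __init__(self, params: list[Tensor], lr: float = 1e-2, momentum: float = 0.9,
                 weight_decay: float = 0.0, clip_norm: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.clip_norm = clip_norm
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        if self.clip_norm:
            clip_global_norm(self.params, self.clip_norm)
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class AdamW:
    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-4):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def step(self) -> None:
        self._t += 1
        b1t = 1.0 - self.b1 ** self._t
        b2t = 1.0 - self.b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
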