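"""Trainable layers built on the autodiff tensor.

Parameters are initialised from a caller-supplied :class:`numpy.random.Generator`
so that every network in the package is reproducible from one master seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d

__all__ = ["Module", "Conv2d", "Linear", "sinusoidal_embedding"]


class Module:
    """Base class: parameter collection and train/eval bookkeeping."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for v in vars(self).values():
            for p in _collect(v):
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"expected {len(params)} arrays, got {len(arrays)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(p.data.dtype).copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


def _collect(v):
    if isinstance(v, Tensor):
        yield v
    elif isinstance(v, Module):
        yield from v.parameters()
    elif isinstance(v, (list, tuple)):
        for item in v:
            yield from _collect(item)


class Conv2d(Module):
    """Conv layer with He-style initialisation."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None, dilation: int = 1):
        fan_in = cin * k * k
        scale = np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, scale, size=(cout, cin, k, k)).astype(np.float32),
                        requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
        self.stride = stride
        self.pad = (k - 1) // 2 * dilation if pad is None else pad
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad,
                      dilation=self.dilation)


class Linear(Module):
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / din)
        self.w = Tensor(rng.normal(0.0, scale, size=(din, dout)).astype(np.float32),
                        requires_grad=True)
        self.b = Tensor(np.zeros(dout, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


def sinusoidal_embedding(s: np.ndarray, dim: int, max_period: float = 10_000.0) -> np.ndarray:
    """Transformer-style sinusoidal embedding of diffusion step indices.

    Parameters
    ----------
    s : array of step indices, shape (N,)
    dim : embedding dimension (even)
    """
    if dim % 2:
        raise ValueError("embedding dimension must be even")
    s = np.asarray(s, dtype=np.float64).reshape(-1, 1)
    freqs = np.exp(-np.log(max_period) * np.arange(dim // 2) / (dim // 2))
    ang = s * freqs[None, :]
    return np.concatenate([np.sin(ang), np.cos(ang)], axis=1).astype(np.float32)
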