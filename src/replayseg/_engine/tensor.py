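"""Minimal reverse-mode automatic differentiation on numpy arrays.

The framework trains small convolutional networks on CPU; this module
provides the graph machinery: a :class:`Tensor` wrapping an ndarray, a
handful of differentiable primitives (broadcast arithmetic, matmul, conv2d
via im2col, pooling, upsampling, log-softmax, L2 normalisation) and a
topological-order backward pass. Gradients of every primitive are checked
against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "avg_pool2",
    "upsample_nearest2",
    "log_softmax",
    "l2_normalize",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph.

    Parameters
    ----------
    data : array-like
        Values; stored as a float ndarray.
    requires_grad : bool
        Whether gradients should be accumulated into ``.grad``.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64 if np.asarray(data).dtype == np.float64 else np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor.__new__(Tensor)
        out.data = data
        out.grad = None
        out.requires_grad = any(p.requires_grad for p in parents)
        out._parents = parents if out.requires_grad else ()
        out._backward = backward if out.requires_grad else None
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float32))

    def __add__(self, other):
        other = self._coerce(other)
        out_data = self.data + other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out_data = self.data * other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g, a=self, p=exponent):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1.0))

        return Tensor._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._coerce(other)
        out_data = self.data @ other.data

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._make(out_data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g, a=self, m=mask):
            if a.requires_grad:
                a._accum(g * m)

        return Tensor._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        return self ** 0.5

    # -- reductions / reshaping -----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g, a=self, ax=axis, kd=keepdims):
            if not a.requires_grad:
                return
            g = np.asarray(g)
            if ax is not None and not kd:
                g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g, a=self, s=old):
            if a.requires_grad:
                a._accum(g.reshape(s))

        return Tensor._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g, a=self, i=idx):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, i, g)
                a._accum(full)

        return Tensor._make(out_data, (self,), backward)

    # -- backward engine ------------------------------------------------------
    def _accum(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        """Run reverse-mode differentiation from this tensor.

        ``grad`` defaults to ones (so a scalar loss needs no argument).
        """
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        self.grad = np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)


# -- structural ops -----------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, ts=tuple(tensors), ax=axis, offs=offsets):
        for k, t in enumerate(ts):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[ax] = slice(offs[k], offs[k + 1])
                t._accum(g[tuple(sl)])

    return Tensor._make(out_data, tuple(tensors), backward)


# -- convolution via im2col ----------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int, dilation: int):
    n, c, h, w = x.shape
    eh, ew = (kh - 1) * dilation + 1, (kw - 1) * dilation + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - eh) // stride + 1
    ow = (w + 2 * pad - ew) // stride + 1
    s0, s1, s2, s3 = x.strides
    shape = (n, c, kh, kw, oh, ow)
    strides = (s0, s1, s2 * dilation, s3 * dilation, s2 * stride, s3 * stride)
    cols = np.lib.stride_tricks.as_strided(x, shape=shape, strides=strides)
    return np.ascontiguousarray(cols), oh, ow


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           pad: int = 0, dilation: int = 1) -> Tensor:
    """2-D convolution, NCHW layout, weight (C_out, C_in, kH, kW)."""
    n, c, h, wdt = x.data.shape
    co, ci, kh, kw = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {ci}")
    cols, oh, ow = _im2col(x.data, kh, kw, stride, pad, dilation)
    cols2 = cols.reshape(n, c * kh * kw, oh * ow)
    wmat = w.data.reshape(co, c * kh * kw)
    out = np.einsum("ok,nkp->nop", wmat, cols2, optimize=True).reshape(n, co, oh, ow)
    if b is not None:
        out = out + b.data.reshape(1, co, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def backward(g, x=x, w=w, b=b, cols2=cols2, wmat=wmat,
                 stride=stride, pad=pad, dilation=dilation,
                 kh=kh, kw=kw, n=n, c=c, h=h, wdt=wdt, oh=oh, ow=ow, co=co):
        gmat = g.reshape(n, co, oh * ow)
        if w.requires_grad:
            gw = np.einsum("nop,nkp->ok", gmat, cols2, optimize=True)
            w._accum(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.einsum("ok,nop->nkp", wmat, gmat, optimize=True)
            gcols = gcols.reshape(n, c, kh, kw, oh, ow)
            hp, wp = h + 2 * pad, wdt + 2 * pad
            gx = np.zeros((n, c, hp, wp), dtype=x.data.dtype)
            for i in range(kh):
                hi = i * dilation
                for j in range(kw):
                    wj = j * dilation
                    gx[:, :, hi:hi + stride * oh:stride, wj:wj + stride * ow:stride] += gcols[:, :, i, j]
            if pad:
                gx = gx[:, :, pad:-pad, pad:-pad]
            x._accum(gx)

    return Tensor._make(out, parents, backward)


def avg_pool2(x: Tensor) -> Tensor:
    """2x2 average pooling, stride 2 (spatial dims must be even)."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("avg_pool2 requires even spatial dimensions")
    out = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(g, a=x, n=n, c=c, h=h, w=w):
        if a.requires_grad:
            gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
            a._accum(gx)

    return Tensor._make(out, (x,), backward)


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)

    def backward(g, a=x):
        if a.requires_grad:
            n, c, h, w = a.data.shape
            a._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), backward)


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    z = x.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse

    def backward(g, a=x, out=out, ax=axis):
        if a.requires_grad:
            soft = np.exp(out)
            a._accum(g - soft * g.sum(axis=ax, keepdims=True))

    return Tensor._make(out, (x,), backward)


def l2_normalize(x: Tensor, axis: int = -1, eps: float = 1e-12) -> Tensor:
    """Normalise rows of ``x`` to unit Euclidean norm."""
    norm = np.sqrt((x.data ** 2).sum(axis=axis, keepdims=True) + eps)
    out = x.data / norm

    def backward(g, a=x, out=out, norm=norm, ax=axis):
        if a.requires_grad:
            dot = (g * out).sum(axis=ax, keepdims=True)
            a._accum((g - out * dot) / norm)

    return Tensor._make(out, (x,), backward)
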