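"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is a tape-based autodiff engine providing exactly the primitives the
gated attention network needs: broadcast arithmetic, batched matmul, shape
ops, softmax/log-softmax, relu/sigmoid, reductions, a strided 2-D
convolution and 2x2 max pooling.  Everything is float64; the models built
on top are small enough that clarity and exactness beat throughput.

Gradients accumulate into ``Tensor.grad`` when :func:`backward` is called
on a scalar loss.  Graphs are ephemeral: build, backprop, discard.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "parameter", "backward",
    "add", "mul", "matmul", "transpose", "reshape", "concat",
    "softmax", "log_softmax", "relu", "sigmoid", "exp", "log",
    "mean", "sum_", "linear", "layer_norm", "conv2d", "maxpool2x2",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._vjp = None  # callable grad_out -> tuple of parent grads

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __truediv__(self, other):
        return mul(self, power(other, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def __getitem__(self, idx):
        return getitem(self, idx)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def parameter(data) -> Tensor:
    return Tensor(data, requires_grad=True)


def _node(data, parents, vjp) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._vjp = vjp
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------- arithmetic

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def vjp(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _node(out, (a, b), vjp)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def vjp(g):
        return (_unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape))

    return _node(out, (a, b), vjp)


def power(a, p) -> Tensor:
    a = as_tensor(a)
    p = float(p)
    out = a.data ** p

    def vjp(g):
        return (g * p * a.data ** (p - 1.0),)

    return _node(out, (a,), vjp)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data @ b.data

    def vjp(g):
        ga = g @ np.swapaxes(b.data, -1, -2)
        gb = np.swapaxes(a.data, -1, -2) @ g
        return _unbroadcast(ga, a.data.shape), _unbroadcast(gb, b.data.shape)

    return _node(out, (a, b), vjp)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out = np.exp(a.data)

    def vjp(g):
        return (g * out,)

    return _node(out, (a,), vjp)


def log(a) -> Tensor:
    a = as_tensor(a)
    out = np.log(a.data)

    def vjp(g):
        return (g / a.data,)

    return _node(out, (a,), vjp)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out = np.maximum(a.data, 0.0)

    def vjp(g):
        return (g * (a.data > 0.0),)

    return _node(out, (a,), vjp)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    x = a.data
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)

    def vjp(g):
        return (g * out * (1.0 - out),)

    return _node(out, (a,), vjp)


# -------------------------------------------------------------------- shapes

def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    out = np.transpose(a.data, axes)
    inv = np.argsort(axes)

    def vjp(g):
        return (np.transpose(g, inv),)

    return _node(out, (a,), vjp)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out = a.data.reshape(shape)

    def vjp(g):
        return (g.reshape(a.data.shape),)

    return _node(out, (a,), vjp)


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    out = a.data[idx]

    def vjp(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        return (ga,)

    return _node(out, (a,), vjp)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def vjp(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(out, tuple(tensors), vjp)


# ---------------------------------------------------------------- reductions

def sum_(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def vjp(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.data.shape).copy(),)

    return _node(out, (a,), vjp)


def mean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = a.data.mean(axis=axis, keepdims=keepdims)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])

    def vjp(g):
        g = np.asarray(g) / n
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, a.data.shape).copy(),)

    return _node(out, (a,), vjp)


# ------------------------------------------------------------------ softmax

def softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    x = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(x)
    out = e / e.sum(axis=axis, keepdims=True)

    def vjp(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        return (out * (g - dot),)

    return _node(out, (a,), vjp)


def log_softmax(a, axis: int = -1) -> Tensor:
    a = as_tensor(a)
    x = a.data - a.data.max(axis=axis, keepdims=True)
    lse = np.log(np.exp(x).sum(axis=axis, keepdims=True))
    out = x - lse

    def vjp(g):
        return (g - np.exp(out) * g.sum(axis=axis, keepdims=True),)

    return _node(out, (a,), vjp)


# ----------------------------------------------------------- composite layers

def linear(x, w, b=None) -> Tensor:
    """``x @ w (+ b)`` with ``w`` of shape (in, out)."""
    out = matmul(x, w)
    return out if b is None else add(out, b)


def layer_norm(x, gamma, beta, eps: float = 1e-6) -> Tensor:
    """Normalize over the last axis, then scale and shift."""
    m = mean(x, axis=-1, keepdims=True)
    d = x - m
    v = mean(mul(d, d), axis=-1, keepdims=True)
    inv = power(add(v, eps), -0.5)
    return add(mul(mul(d, inv), gamma), beta)


# -------------------------------------------------------------- convolution

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int, ho: int, wo: int):
    b, c, _, _ = xp.shape
    s0, s1, s2, s3 = xp.strides
    shape = (b, c, kh, kw, ho, wo)
    strides = (s0, s1, s2, s3, s2 * stride, s3 * stride)
    return np.lib.stride_tricks.as_strided(xp, shape=shape, strides=strides)


def conv2d(x, w, b=None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution; ``x`` (B,C,H,W), ``w`` (O,C,kh,kw), ``b`` (O,)."""
    x, w = as_tensor(x), as_tensor(w)
    bt = as_tensor(b) if b is not None else None
    o, c, kh, kw = w.data.shape
    xb, xc, h, ww_ = x.data.shape
    if xc != c:
        raise ValueError(f"conv2d channel mismatch: input {xc}, weight {c}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (ww_ + 2 * pad - kw) // stride + 1
    cols = _im2col(xp, kh, kw, stride, ho, wo)
    out = np.einsum("ockl,bcklhw->bohw", w.data, cols, optimize=True)
    if bt is not None:
        out = out + bt.data[None, :, None, None]

    parents = (x, w) if bt is None else (x, w, bt)

    def vjp(g):
        gw = np.einsum("bohw,bcklhw->ockl", g, cols, optimize=True)
        dcols = np.einsum("ockl,bohw->bcklhw", w.data, g, optimize=True)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += dcols[:, :, i, j]
        gx = gxp[:, :, pad:pad + h, pad:pad + ww_] if pad else gxp
        if bt is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))

    return _node(out, parents, vjp)


def maxpool2x2(x) -> Tensor:
    """2x2 max pooling with stride 2 on (B,C,H,W); H and W must be even."""
    x = as_tensor(x)
    b, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool2x2 requires even spatial dimensions")
    win = x.data.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(b, c, h // 2, w // 2, 4)
    idx = win.argmax(axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def vjp(g):
        gwin = np.zeros((b, c, h // 2, w // 2, 4))
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return (gx.reshape(b, c, h, w),)

    return _node(out, (x,), vjp)


# ----------------------------------------------------------------- backward

def backward(loss: Tensor) -> None:
    """Backpropagate from a scalar ``loss``, accumulating into ``.grad``."""
    if loss.data.size != 1:
        raise ValueError("backward() expects a scalar loss")
    topo: list[Tensor] = []
    seen: set[int] = set()
    stack = [(loss, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen or not node.requires_grad:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            stack.append((p, False))

    grads: dict[int, np.ndarray] = {id(loss): np.ones_like(loss.data)}
    for node in reversed(topo):
        g = grads.pop(id(node), None)
        if g is None:
            continue
        if node._vjp is not None:
            for p, pg in zip(node._parents, node._vjp(g)):
                if not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg
        else:  # leaf parameter
            node.grad = pg_accum(node.grad, g)


def pg_accum(existing, g):
    return g.copy() if existing is None else existing + g
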