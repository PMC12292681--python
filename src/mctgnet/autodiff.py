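"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and
records the operations applied to it; :meth:`Tensor.backward` walks the
recorded graph in reverse topological order and accumulates gradients.
Only the operations the network needs are provided — broadcasting
arithmetic, matmul, reductions, shape ops, a numerically stable softmax,
ELU, and FFT-based temporal convolutions.

Gradients follow numpy broadcasting semantics: a gradient flowing into a
broadcast operand is summed over the broadcast axes.
"""

from __future__ import annotations

import contextlib

import numpy as np
from scipy import fft as _fft

__all__ = [
    "Tensor",
    "as_tensor",
    "no_grad",
    "concatenate",
    "softmax",
    "elu",
    "pad_last",
    "temporal_filterbank",
    "depthwise_time_conv",
]

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph recording."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` to ``shape`` by summing over broadcast axes."""
    if grad.shape == shape:
        return grad
    # sum away leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were size-1 in the original
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """An ndarray with an optional gradient and a backward recipe."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64) if not isinstance(
            data, np.ndarray
        ) else data
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def backward(self, grad=None):
        """Backpropagate from this tensor; frees the graph afterwards."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo, seen = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if pgrad is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = pgrad
                else:
                    parent.grad = parent.grad + pgrad
            # release graph memory as we go
            node._parents = ()
            node._backward = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ----------------------------------------------------------------------
# arithmetic
# ----------------------------------------------------------------------
# python scalars keep "weak" promotion (a float32 graph stays float32),
# so they get dedicated constant ops instead of being wrapped in arrays
def _add_const(a: Tensor, c) -> Tensor:
    return _node(a.data + float(c), (a,), lambda g: (g,))


def _mul_const(a: Tensor, c) -> Tensor:
    c = float(c)
    return _node(a.data * c, (a,), lambda g: (g * c,))


def _rdiv_const(c, a: Tensor) -> Tensor:
    out = float(c) / a.data
    return _node(out, (a,), lambda g: (-g * out / a.data,))


def _is_scalar(x) -> bool:
    # numpy float scalars subclass python float but promote "strongly",
    # so they are routed here too and coerced with float()
    return isinstance(x, (int, float, np.floating)) and not isinstance(x, bool)


def _add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _node(a.data + b.data, (a, b), bw)


def _mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        return _unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)

    return _node(a.data * b.data, (a, b), bw)


def _div(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        ga = _unbroadcast(g / b.data, a.shape)
        gb = _unbroadcast(-g * a.data / (b.data * b.data), b.shape)
        return ga, gb

    return _node(a.data / b.data, (a, b), bw)


def _neg(a: Tensor) -> Tensor:
    return _node(-a.data, (a,), lambda g: (-g,))


def _matmul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        ga = gb = None
        if a.requires_grad:
            ga = _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.shape)
        if b.requires_grad:
            gb = _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.shape)
        return ga, gb

    return _node(a.data @ b.data, (a, b), bw)


def _pow(a: Tensor, exponent: float) -> Tensor:
    out = a.data**exponent

    def bw(g):
        return (g * exponent * a.data ** (exponent - 1),)

    return _node(out, (a,), bw)


def _binary(self, other, tensor_op, const_op):
    if _is_scalar(other):
        return const_op(self, other)
    return tensor_op(self, as_tensor(other))


Tensor.__add__ = lambda self, other: _binary(self, other, _add, _add_const)
Tensor.__radd__ = Tensor.__add__
Tensor.__sub__ = lambda self, other: _binary(
    self, other, lambda a, b: _add(a, _neg(b)), lambda a, c: _add_const(a, -c)
)
Tensor.__rsub__ = lambda self, other: (
    _add_const(_neg(self), other) if _is_scalar(other) else _add(as_tensor(other), _neg(self))
)
Tensor.__mul__ = lambda self, other: _binary(self, other, _mul, _mul_const)
Tensor.__rmul__ = Tensor.__mul__
Tensor.__truediv__ = lambda self, other: _binary(
    self, other, _div, lambda a, c: _mul_const(a, 1.0 / c)
)
Tensor.__rtruediv__ = lambda self, other: (
    _rdiv_const(other, self) if _is_scalar(other) else _div(as_tensor(other), self)
)
Tensor.__neg__ = _neg
Tensor.__matmul__ = lambda self, other: _matmul(self, as_tensor(other))
Tensor.__pow__ = _pow


# ----------------------------------------------------------------------
# elementwise
# ----------------------------------------------------------------------
def _t_abs(a: Tensor) -> Tensor:
    return _node(np.abs(a.data), (a,), lambda g: (g * np.sign(a.data),))


def _t_exp(a: Tensor) -> Tensor:
    out = np.exp(a.data)
    return _node(out, (a,), lambda g: (g * out,))


def _t_log(a: Tensor) -> Tensor:
    return _node(np.log(a.data), (a,), lambda g: (g / a.data,))


def _t_sqrt(a: Tensor) -> Tensor:
    out = np.sqrt(a.data)
    return _node(out, (a,), lambda g: (g * 0.5 / out,))


def elu(a: Tensor, alpha: float = 1.0) -> Tensor:
    a = as_tensor(a)
    pos = a.data > 0
    out = np.where(pos, a.data, alpha * np.expm1(np.minimum(a.data, 0.0)))

    def bw(g):
        return (g * np.where(pos, 1.0, out + alpha),)

    return _node(out, (a,), bw)


Tensor.abs = _t_abs
Tensor.exp = _t_exp
Tensor.log = _t_log
Tensor.sqrt = _t_sqrt


# ----------------------------------------------------------------------
# reductions and shape ops
# ----------------------------------------------------------------------
def _t_sum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        if axis is None:
            return (np.broadcast_to(g, a.shape).copy(),)
        ax = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, ax)
        return (np.broadcast_to(g, a.shape).copy(),)

    return _node(out, (a,), bw)


def _t_mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        count = a.size
    else:
        ax = axis if isinstance(axis, tuple) else (axis,)
        count = int(np.prod([a.shape[i] for i in ax]))
    return _t_sum(a, axis=axis, keepdims=keepdims) * (1.0 / count)


def _t_reshape(a: Tensor, *shape) -> Tensor:
    if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
        shape = tuple(shape[0])
    return _node(a.data.reshape(shape), (a,), lambda g: (g.reshape(a.shape),))


def _t_transpose(a: Tensor, *axes) -> Tensor:
    if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
        axes = tuple(axes[0])
    inv = np.argsort(axes)
    return _node(a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),))


def _t_getitem(a: Tensor, key) -> Tensor:
    def bw(g):
        out = np.zeros_like(a.data)
        out[key] += g
        return (out,)

    return _node(a.data[key], (a,), bw)


Tensor.sum = _t_sum
Tensor.mean = _t_mean
Tensor.reshape = _t_reshape
Tensor.transpose = _t_transpose
Tensor.__getitem__ = _t_getitem


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tensors, bw)


def pad_last(a: Tensor, left: int, right: int) -> Tensor:
    """Zero-pad the last axis."""
    a = as_tensor(a)
    width = [(0, 0)] * (a.ndim - 1) + [(left, right)]
    n = a.shape[-1]

    def bw(g):
        return (g[..., left : left + n],)

    return _node(np.pad(a.data, width), (a,), bw)


def channel_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused batch normalization over axes (0, 2) of a (B, C, T) map.

    Returns (out, mean, var); the analytic backward avoids the long chain
    of elementwise temporaries a composed implementation would record.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    n = x.shape[0] * x.shape[2]
    mean = x.data.mean(axis=(0, 2))
    xc = x.data - mean[None, :, None]
    var = np.mean(xc * xc, axis=(0, 2))
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv[None, :, None]
    out = xhat * gamma.data[None, :, None] + beta.data[None, :, None]

    def bw(g):
        gx = ggamma = gbeta = None
        if gamma.requires_grad:
            ggamma = (g * xhat).sum(axis=(0, 2))
        if beta.requires_grad:
            gbeta = g.sum(axis=(0, 2))
        if x.requires_grad:
            gh = g * gamma.data[None, :, None]
            s1 = gh.sum(axis=(0, 2))
            s2 = (gh * xhat).sum(axis=(0, 2))
            gx = inv[None, :, None] * (
                gh - (s1[None, :, None] + xhat * s2[None, :, None]) / n
            )
        return gx, ggamma, gbeta

    return _node(out, (x, gamma, beta), bw), mean, var


def softmax(a: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax with analytic Jacobian-vector product."""
    a = as_tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        return (out * (g - (g * out).sum(axis=axis, keepdims=True)),)

    return _node(out, (a,), bw)


# ----------------------------------------------------------------------
# FFT-based temporal convolutions (cross-correlation, "same" padding)
# ----------------------------------------------------------------------
def _rfft_len(n: int) -> int:
    return _fft.next_fast_len(n, real=True)


def temporal_filterbank(x: Tensor, w: Tensor) -> Tensor:
    """Apply a bank of temporal filters to every channel of every trial.

    ``x`` has shape (B, C, T) and ``w`` shape (F, K).  The output
    ``y[b, f, c, t] = sum_k w[f, k] * x[b, c, t + k - pl]`` with
    ``pl = (K - 1) // 2`` and zero padding ("same" length).  Computed via
    real FFTs, which on CPU is far cheaper than explicit sliding windows
    for the kernel lengths used here (32–96 taps on 1000-sample trials).
    """
    x, w = as_tensor(x), as_tensor(w)
    B, C, T = x.shape
    F, K = w.shape
    pl = (K - 1) // 2
    nfft = _rfft_len(T + K - 1)
    xf = _fft.rfft(x.data, nfft, axis=-1)  # (B, C, nf)
    wf_rev = _fft.rfft(w.data[:, ::-1], nfft, axis=-1)  # (F, nf)
    full = _fft.irfft(xf[:, None, :, :] * wf_rev[None, :, None, :], nfft, axis=-1)
    off = K - 1 - pl
    y = full[..., off : off + T]

    def bw(g):
        gx = gw = None
        gf = _fft.rfft(g, nfft, axis=-1)  # (B, F, C, nf)
        if x.requires_grad:
            wf = _fft.rfft(w.data, nfft, axis=-1)
            acc = (gf * wf[None, :, None, :]).sum(axis=1)  # (B, C, nf)
            conv = _fft.irfft(acc, nfft, axis=-1)
            gx = conv[..., pl : pl + T]
        if w.requires_grad:
            # dW[f,k] = sum_{b,c,t} g[b,f,c,t] x[b,c,t+k-pl]  (circular corr)
            corr = _fft.irfft(
                (np.conj(gf) * xf[:, None, :, :]).sum(axis=(0, 2)), nfft, axis=-1
            )  # (F, nfft)
            idx = (np.arange(K) - pl) % nfft
            gw = corr[:, idx]
        return gx, gw

    return _node(y, (x, w), bw)


def depthwise_time_conv(x: Tensor, w: Tensor) -> Tensor:
    """Per-channel temporal convolution: x (B, CH, T), w (CH, K) -> (B, CH, T).

    Same semantics as :func:`temporal_filterbank` but each channel has its
    own filter and the channel axis is preserved.
    """
    x, w = as_tensor(x), as_tensor(w)
    B, CH, T = x.shape
    CHw, K = w.shape
    if CHw != CH:
        raise ValueError(f"filter channels {CHw} != input channels {CH}")
    pl = (K - 1) // 2
    nfft = _rfft_len(T + K - 1)
    xf = _fft.rfft(x.data, nfft, axis=-1)  # (B, CH, nf)
    wf_rev = _fft.rfft(w.data[:, ::-1], nfft, axis=-1)  # (CH, nf)
    full = _fft.irfft(xf * wf_rev[None], nfft, axis=-1)
    off = K - 1 - pl
    y = full[..., off : off + T]

    def bw(g):
        gx = gw = None
        gf = _fft.rfft(g, nfft, axis=-1)
        if x.requires_grad:
            wf = _fft.rfft(w.data, nfft, axis=-1)
            gx = _fft.irfft(gf * wf[None], nfft, axis=-1)[..., pl : pl + T]
        if w.requires_grad:
            corr = _fft.irfft((np.conj(gf) * xf).sum(axis=0), nfft, axis=-1)
            idx = (np.arange(K) - pl) % nfft
            gw = corr[:, idx]
        return gx, gw

    return _node(y, (x, w), bw)
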