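"""Neural-network building blocks on top of :mod:`mctgnet.autodiff`.

Provides the torch-like ``Module`` container plus the handful of layers
the decoder needs: linear maps, batch/layer normalization, dropout, and
the Adam optimizer.  Parameters are plain :class:`~mctgnet.autodiff.Tensor`
objects with ``requires_grad=True``; modules are discovered by attribute
scanning, so checkpoints are keyed by dotted attribute paths.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor, channel_norm

__all__ = ["Parameter", "Module", "Linear", "BatchNorm", "LayerNorm", "Dropout", "Adam"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    # -- traversal -----------------------------------------------------
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Parameter):
                        yield f"{prefix}{name}.{i}", item
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    # -- modes ---------------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization -------------------------------------------------
    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        unexpected = set(state) - set(own)
        if missing or unexpected:
            raise KeyError(f"state mismatch: missing={sorted(missing)} unexpected={sorted(unexpected)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def astype(self, dtype):
        """Cast parameters and float buffers (e.g. running stats) in place."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for m in self.modules():
            for k, v in vars(m).items():
                if isinstance(v, np.ndarray) and not isinstance(v, Tensor) and v.dtype.kind == "f":
                    setattr(m, k, v.astype(dtype))
        return self

    @property
    def dtype(self):
        return next(self.parameters()).data.dtype

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Affine map on the last axis, fan-in scaled Gaussian init."""

    def __init__(self, din: int, dout: int, bias: bool = True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.weight = Parameter(rng.standard_normal((din, dout)) / np.sqrt(din))
        self.bias = Parameter(np.zeros(dout)) if bias else None

    def forward(self, x):
        out = as_tensor(x) @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm(Module):
    """Batch normalization for (B, C, T) feature maps (per-channel stats)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x):
        x = as_tensor(x)
        if self.training:
            out, mean, var = channel_norm(x, self.gamma, self.beta, self.eps)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(
                x.data.dtype
            )
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                x.data.dtype
            )
            return out
        mean = self.running_mean[None, :, None]
        std = np.sqrt(self.running_var + self.eps)[None, :, None]
        xhat = (x - mean) * (1.0 / std)
        g = self.gamma.reshape(1, -1, 1)
        b = self.beta.reshape(1, -1, 1)
        return xhat * g + b


class LayerNorm(Module):
    """Normalization over the last (embedding) axis."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x):
        x = as_tensor(x)
        mean = x.mean(axis=-1, keepdims=True)
        var = ((x - mean) ** 2).mean(axis=-1, keepdims=True)
        xhat = (x - mean) / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta


class Dropout(Module):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng=None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x):
        x = as_tensor(x)
        if not self.training or self.p == 0.0:
            return x
        mask = ((self.rng.random(x.shape) >= self.p) / (1.0 - self.p)).astype(x.data.dtype)
        return x * mask


class Adam:
    """Adam optimizer (Kingma & Ba) with bias correction."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
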