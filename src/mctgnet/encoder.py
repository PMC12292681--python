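"""Local-global KAN-transformer (LG-KAT) encoder.

Each encoder layer runs two scaled dot-product attention paths over the
feature sequence: a *global* path whose keys are a plain linear
projection, and a *local* path whose keys are first enriched by two
small 1-D convolutions along the sequence axis (kernels 3 and 5 by
default, each emitting E/2 channels so their concatenation preserves the
embedding width).  The two attention outputs are fused by element-wise
addition and projected.  The feed-forward sublayer is replaced by a pair
of GR-KAN layers (expansion E -> r*E -> E).

Sinusoidal positional encoding is added once before the first layer.
Residual connections use pre-norm ordering by default (normalization
inside the residual branch), which trains more stably at depth; the
classic post-norm ordering is available via ``AttentionConfig.prenorm``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import nn
from .autodiff import Tensor, as_tensor, concatenate, no_grad, pad_last, softmax
from .grkan import RationalGroupLayer

__all__ = [
    "AttentionConfig",
    "sinusoidal_pe",
    "scaled_dot_attention",
    "LocalKeyTransform",
    "LGAttention",
    "EncoderLayer",
    "LGKATEncoder",
    "local_key_transform",
    "lg_attention_block",
]


@dataclass
class AttentionConfig:
    embed_dim: int = 16
    heads: int = 4
    local_kernels: Tuple[int, int] = (3, 5)
    layers: int = 1
    dropout: float = 0.5
    prenorm: bool = True
    mixer_expansion: int = 4
    mixer_groups: int = 8

    def __post_init__(self):
        self.local_kernels = tuple(int(k) for k in self.local_kernels)
        if self.embed_dim % self.heads != 0:
            raise ValueError(f"embed_dim {self.embed_dim} not divisible by heads {self.heads}")
        if self.embed_dim % 2 != 0:
            raise ValueError("embed_dim must be even (local keys split across two branches)")
        if any(k % 2 == 0 or k < 1 for k in self.local_kernels):
            raise ValueError(f"local kernels must be odd and positive, got {self.local_kernels}")
        if self.layers < 0:
            raise ValueError("layers must be >= 0")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.heads


def sinusoidal_pe(length: int, width: int) -> np.ndarray:
    """Absolute sinusoidal positional encoding.

    PE[pos, 2i] = sin(pos / 10000^(2i/width)),
    PE[pos, 2i + 1] = cos(pos / 10000^(2i/width)).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if width < 2 or width % 2 != 0:
        raise ValueError(f"width must be even and >= 2, got {width}")
    pos = np.arange(length)[:, None]
    i = np.arange(width // 2)[None, :]
    angle = pos / np.power(10000.0, 2.0 * i / width)
    pe = np.empty((length, width))
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def scaled_dot_attention(q, k, v, return_weights: bool = False):
    """softmax(Q K^T / sqrt(d_k)) V over (..., L, d_k) arrays or tensors.

    Returns an array when given arrays, a Tensor when given Tensors (so it
    can sit inside a recorded graph).  Softmax rows sum to one.
    """
    tensor_in = any(isinstance(t, Tensor) for t in (q, k, v))
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    if not (q.shape == k.shape == v.shape):
        raise ValueError("q, k, v must share the same shape")
    if tensor_in:
        return _sdp(q, k, v, return_weights=return_weights)
    with no_grad():
        out = _sdp(q, k, v, return_weights=return_weights)
    if return_weights:
        return out[0].data, out[1].data
    return out.data


def _split_heads(x: Tensor, heads: int) -> Tensor:
    b, l, e = x.shape
    return x.reshape(b, l, heads, e // heads).transpose(0, 2, 1, 3)


def _merge_heads(x: Tensor) -> Tensor:
    b, h, l, dk = x.shape
    return x.transpose(0, 2, 1, 3).reshape(b, l, h * dk)


class LocalKeyTransform(nn.Module):
    """Two 1-D convolutions along the sequence axis, concatenated.

    Each convolution maps E input channels to E/2 output channels with an
    odd kernel and zero "same" padding, so the output has the same (B, L,
    E) shape as the input.  Implemented as a sum of shifted linear maps,
    which is exact for the short kernels used here.
    """

    def __init__(self, embed_dim: int, kernels: Tuple[int, int] = (3, 5), rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        if embed_dim % 2 != 0:
            raise ValueError("embed_dim must be even")
        self.embed_dim = embed_dim
        self.kernels = tuple(kernels)
        half = embed_dim // 2
        self.weights = [
            nn.Parameter(rng.standard_normal((k, embed_dim, half)) / np.sqrt(k * embed_dim))
            for k in self.kernels
        ]

    def _conv(self, x: Tensor, w: nn.Parameter, kernel: int) -> Tensor:
        # x: (B, L, E); shift-and-sum along L with zero padding
        b, l, e = x.shape
        xp = pad_last(x.transpose(0, 2, 1), kernel // 2, kernel // 2)  # (B, E, L+k-1)
        out = None
        for j in range(kernel):
            term = xp[:, :, j : j + l].transpose(0, 2, 1) @ w[j]
            out = term if out is None else out + term
        return out  # (B, L, E/2)

    def forward(self, x):
        x = as_tensor(x)
        parts = [self._conv(x, w, k) for w, k in zip(self.weights, self.kernels)]
        return concatenate(parts, axis=-1)


class LGAttention(nn.Module):
    """Multi-head attention with additive local/global key fusion.

    All projections are bias-free so the block is exactly linear in the
    value path; the two per-head attention outputs are summed and passed
    through a single output projection.
    """

    def __init__(self, config: AttentionConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        e = config.embed_dim
        self.config = config
        self.wq = nn.Linear(e, e, bias=False, rng=rng)
        self.wk = nn.Linear(e, e, bias=False, rng=rng)
        self.wv = nn.Linear(e, e, bias=False, rng=rng)
        self.local_keys = LocalKeyTransform(e, config.local_kernels, rng=rng)
        self.out = nn.Linear(e, e, bias=False, rng=rng)
        self.drop = nn.Dropout(config.dropout, rng=np.random.default_rng(rng.integers(2**31)))

    def forward(self, x):
        x = as_tensor(x)
        h = self.config.heads
        q = _split_heads(self.wq(x), h)
        kg = _split_heads(self.wk(x), h)
        kl = _split_heads(self.local_keys(x), h)
        v = _split_heads(self.wv(x), h)
        att_local = _sdp(q, kl, v)
        att_global = _sdp(q, kg, v)
        fused = _merge_heads(att_local + att_global)
        return self.drop(self.out(fused))


def _sdp(q: Tensor, k: Tensor, v: Tensor, return_weights: bool = False):
    dk = q.shape[-1]
    if dk == 0:
        raise ValueError("head dimension must be positive")
    scores = (q @ k.transpose(*range(q.ndim - 2), q.ndim - 1, q.ndim - 2)) * (1.0 / np.sqrt(dk))
    weights = softmax(scores, axis=-1)
    out = weights @ v
    return (out, weights) if return_weights else out


class EncoderLayer(nn.Module):
    """Attention sublayer + GR-KAN channel-mixer sublayer with residuals."""

    def __init__(self, config: AttentionConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        e = config.embed_dim
        self.config = config
        self.norm1 = nn.LayerNorm(e)
        self.attn = LGAttention(config, rng=rng)
        self.norm2 = nn.LayerNorm(e)
        hidden = config.mixer_expansion * e
        self.mixer_in = RationalGroupLayer(
            e, hidden, groups=config.mixer_groups, seed=int(rng.integers(2**31))
        )
        self.mixer_out = RationalGroupLayer(
            hidden, e, groups=config.mixer_groups, seed=int(rng.integers(2**31))
        )
        self.drop = nn.Dropout(config.dropout, rng=np.random.default_rng(rng.integers(2**31)))

    def _mix(self, x):
        return self.mixer_out(self.mixer_in(x))

    def forward(self, x):
        x = as_tensor(x)
        if self.config.prenorm:
            x = x + self.attn(self.norm1(x))
            x = x + self.drop(self._mix(self.norm2(x)))
        else:
            x = self.norm1(x + self.attn(x))
            x = self.norm2(x + self.drop(self._mix(x)))
        return x


class LGKATEncoder(nn.Module):
    """Positional encoding plus a stack of encoder layers."""

    def __init__(self, config: AttentionConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.config = config
        self.layers = [EncoderLayer(config, rng=rng) for _ in range(config.layers)]

    def forward(self, x):
        x = as_tensor(x)
        x = x + sinusoidal_pe(x.shape[1], x.shape[2]).astype(x.data.dtype)
        for layer in self.layers:
            x = layer(x)
        return x


# ----------------------------------------------------------------------
# functional views
# ----------------------------------------------------------------------
def local_key_transform(
    x: np.ndarray,
    config: Optional[AttentionConfig] = None,
    *,
    module: Optional[LocalKeyTransform] = None,
    seed: int = 0,
) -> np.ndarray:
    """Apply the local-key convolutions to a (B, L, E) array."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("input must be finite")
    if module is None:
        config = config or AttentionConfig(embed_dim=x.shape[-1])
        module = LocalKeyTransform(
            config.embed_dim, config.local_kernels, rng=np.random.default_rng(seed)
        )
    with no_grad():
        return module(Tensor(x)).data


def lg_attention_block(
    x: np.ndarray,
    config: Optional[AttentionConfig] = None,
    *,
    module: Optional[LGAttention] = None,
    seed: int = 0,
) -> np.ndarray:
    """Run one local-global attention block on a (B, L, E) array (eval mode)."""
    x = np.asarray(x, dtype=np.float64)
    config = config or AttentionConfig(embed_dim=x.shape[-1])
    if module is None:
        module = LGAttention(config, rng=np.random.default_rng(seed))
    module.eval()
    with no_grad():
        return module(Tensor(x)).data
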