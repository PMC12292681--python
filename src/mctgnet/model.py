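"""End-to-end motor-imagery decoder.

Pipeline: multi-scale CNN front-end -> LG-KAT encoder -> residual fusion
of the embedded and encoded sequences (element-wise addition) -> flatten
-> a single GR-KAN classifier head mapping the L*E feature vector to N
class logits.  Softmax lives inside the cross-entropy loss; the forward
pass returns raw logits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .autodiff import Tensor, as_tensor, no_grad
from . import nn
from .backbone import (
    EEGDataset,
    KERNELS_BINARY,
    KERNELS_FOUR_CLASS,
    MPEBackbone,
    MultiScaleConfig,
    output_length,
)
from .encoder import AttentionConfig, LGKATEncoder
from .grkan import RationalGroupLayer

__all__ = ["ModelConfig", "MCTGNet", "forward", "cross_entropy_loss", "Logits"]


@dataclass
class ModelConfig:
    """Everything needed to build the decoder for a given montage."""

    channels: int = 22
    samples: int = 1000
    classes: int = 4
    backbone: MultiScaleConfig = field(default_factory=MultiScaleConfig)
    encoder: AttentionConfig = field(default_factory=AttentionConfig)
    head_groups: int = 8
    # per-trial channel standardization at the model input; cancels
    # per-channel gain/offset drift between recording sessions
    standardize_input: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.classes < 2:
            raise ValueError("need at least two classes")
        if self.backbone.embed_dim != self.encoder.embed_dim:
            raise ValueError(
                f"backbone embedding {self.backbone.embed_dim} != "
                f"encoder embedding {self.encoder.embed_dim}"
            )
        flat = self.flattened_width
        if flat % self.head_groups != 0:
            raise ValueError(
                f"flattened width L*E = {flat} is not divisible by "
                f"head_groups = {self.head_groups}"
            )

    @property
    def sequence_length(self) -> int:
        return output_length(self.samples, self.backbone)

    @property
    def flattened_width(self) -> int:
        return self.sequence_length * self.backbone.embed_dim

    # presets matching the two benchmark montages
    @classmethod
    def four_class(cls, seed: int = 0, **kw) -> "ModelConfig":
        """22-channel, 4-class montage: long kernel triple, 1 encoder layer."""
        return cls(
            channels=22, samples=1000, classes=4,
            backbone=MultiScaleConfig(kernels=KERNELS_FOUR_CLASS),
            encoder=AttentionConfig(layers=1),
            seed=seed, **kw,
        )

    @classmethod
    def binary(cls, seed: int = 0, **kw) -> "ModelConfig":
        """3-channel, 2-class montage: short kernel triple, 5 encoder layers."""
        return cls(
            channels=3, samples=1000, classes=2,
            backbone=MultiScaleConfig(kernels=KERNELS_BINARY),
            encoder=AttentionConfig(layers=5),
            seed=seed, **kw,
        )


@dataclass
class Logits:
    """Raw (pre-softmax) class scores, one row per trial."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("logits must be (B, N)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("logits contain non-finite values")

    def predictions(self) -> np.ndarray:
        return self.values.argmax(axis=1)


class MCTGNet(nn.Module):
    """Backbone + encoder + residual fusion + GR-KAN head."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.backbone = MPEBackbone(config.channels, config.backbone, rng=rng)
        self.encoder = LGKATEncoder(config.encoder, rng=rng)
        self.head = RationalGroupLayer(
            config.flattened_width,
            config.classes,
            groups=config.head_groups,
            seed=int(rng.integers(2**31)),
        )

    def preprocess(self, x):
        """Per-trial, per-channel z-scoring (identity when disabled)."""
        x = as_tensor(x)
        if not self.config.standardize_input:
            return x
        mean = x.mean(axis=-1, keepdims=True)
        centered = x - mean
        std = ((centered**2).mean(axis=-1, keepdims=True) + 1e-12).sqrt()
        return centered / std

    def forward(self, x):
        x = as_tensor(x)
        b, c, t = x.shape
        if c != self.config.channels or t != self.config.samples:
            raise ValueError(
                f"input {c} channels x {t} samples; model expects "
                f"{self.config.channels} x {self.config.samples}"
            )
        embed = self.backbone(self.preprocess(x))  # (B, L, E)
        att = self.encoder(embed)  # (B, L, E)
        fused = embed + att
        flat = fused.reshape(b, self.config.flattened_width)
        return self.head(flat)  # (B, N)

    def features(self, trials: np.ndarray) -> np.ndarray:
        """Flattened pre-head features (for inspection / t-SNE export)."""
        self.eval()
        with no_grad():
            x = self.preprocess(Tensor(np.asarray(trials, dtype=self.dtype)))
            embed = self.backbone(x)
            fused = embed + self.encoder(embed)
            return fused.data.reshape(len(trials), -1)


def forward(dataset: EEGDataset, config: ModelConfig, model: Optional[MCTGNet] = None) -> Logits:
    """Build (or reuse) a model and run it over a dataset in eval mode."""
    if model is None:
        model = MCTGNet(config)
    model.eval()
    with no_grad():
        return Logits(model(Tensor(dataset.trials)).data)


def cross_entropy_loss(logits, labels):
    """Mean cross-entropy −(1/M) Σ_i log softmax(logits_i)[y_i].

    Accepts a Tensor (returns a scalar Tensor attached to the graph) or a
    plain array / :class:`Logits` (returns a float).
    """
    if isinstance(logits, Logits):
        logits = logits.values
    labels = np.asarray(labels, dtype=np.int64)
    values = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    m, n = values.shape
    if labels.shape != (m,):
        raise ValueError("need one label per logit row")
    if labels.size and (labels.min() < 0 or labels.max() >= n):
        raise ValueError(f"labels must lie in [0, {n})")

    def _loss(t: Tensor) -> Tensor:
        shift = t - t.data.max(axis=1, keepdims=True)  # constant shift, stabilizes exp
        log_z = shift.exp().sum(axis=1, keepdims=True).log()
        log_p = shift - log_z
        onehot = np.eye(n, dtype=t.data.dtype)[labels]
        return -(log_p * onehot).sum(axis=1).mean()

    if isinstance(logits, Tensor):
        return _loss(logits)
    with no_grad():
        return float(_loss(Tensor(values)).data)
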