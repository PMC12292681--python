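"""Multi-scale perception CNN (MPE-CNN) front-end.

Raw multi-channel trials (B, C, T) pass through three parallel temporal
convolution branches with short/medium/long kernels, a depthwise spatial
convolution that collapses the electrode axis, two average-pooling
stages separated by a depthwise temporal refinement convolution, and a
1x1 fusion convolution that compresses the concatenated branches into a
feature sequence of shape (B, L, E) with L = floor(floor(T/P1)/P2).

Temporal convolutions use "same" zero padding; pooling windows are
non-overlapping with floor division, so L depends only on (T, P1, P2).
Normalization is batch-style with ELU nonlinearity, the usual convention
for EEG decoders of this family; convolutions are bias-free because each
is followed by a normalization that absorbs any offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from . import nn
from .autodiff import (
    Tensor,
    as_tensor,
    concatenate,
    depthwise_time_conv,
    elu,
    no_grad,
)

__all__ = [
    "EEGDataset",
    "MultiScaleConfig",
    "FeatureSequence",
    "MultiScaleBranch",
    "MPEBackbone",
    "branch_forward",
    "fuse_and_embed",
    "avg_pool",
    "output_length",
    "KERNELS_FOUR_CLASS",
    "KERNELS_BINARY",
]

# kernel presets: long kernels suit the 22-channel 4-class montage,
# shorter ones the 3-channel binary montage
KERNELS_FOUR_CLASS: Tuple[int, int, int] = (32, 64, 96)
KERNELS_BINARY: Tuple[int, int, int] = (16, 32, 64)


@dataclass
class EEGDataset:
    """Labeled multi-channel EEG trials.

    ``trials`` is a (B, C, T) array of microvolt-scale samples, ``labels``
    a length-B integer vector of class indices.  This is the unit of
    exchange between the generator, the augmenter and the trainer, for
    both synthetic and real recordings.
    """

    trials: np.ndarray
    labels: np.ndarray
    sampling_rate: float = 250.0
    subject_id: Optional[str] = None
    session_id: Optional[str] = None

    def __post_init__(self):
        self.trials = np.asarray(self.trials, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.trials.ndim != 3:
            raise ValueError(f"trials must be (B, C, T), got shape {self.trials.shape}")
        if self.labels.shape != (self.trials.shape[0],):
            raise ValueError("labels must be one per trial")
        if not np.all(np.isfinite(self.trials)):
            raise ValueError("trials contain non-finite samples")
        if self.labels.size and self.labels.min() < 0:
            raise ValueError("labels must be nonnegative class indices")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def __len__(self) -> int:
        return self.n_trials

    def subset(self, idx) -> "EEGDataset":
        return EEGDataset(
            self.trials[idx], self.labels[idx], self.sampling_rate,
            self.subject_id, self.session_id,
        )


@dataclass
class MultiScaleConfig:
    """Hyperparameters of the CNN front-end (named after the usual EEG-CNN
    conventions: F1 temporal filters, depth multiplier D, kernel triple K1,
    pooling sizes P1/P2, refinement kernel K2, embedding E)."""

    f1: int = 8
    depth_multiplier: int = 2
    kernels: Tuple[int, int, int] = KERNELS_FOUR_CLASS
    pool1: int = 8
    refine_kernel: int = 16
    pool2: int = 8
    embed_dim: int = 16
    dropout: float = 0.25

    def __post_init__(self):
        self.kernels = tuple(int(k) for k in self.kernels)
        # three branches is the architecture; a one-element tuple builds the
        # single-scale ablation baseline (one branch, one kernel)
        if len(self.kernels) not in (1, 3) or any(k < 1 for k in self.kernels) or not all(
            a <= b for a, b in zip(self.kernels, self.kernels[1:])
        ):
            raise ValueError(
                f"kernels must be a non-decreasing triple (or a single kernel "
                f"for the single-scale variant), got {self.kernels}"
            )
        for name in ("f1", "depth_multiplier", "pool1", "refine_kernel", "pool2", "embed_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def branch_channels(self) -> int:
        return self.f1 * self.depth_multiplier


@dataclass
class FeatureSequence:
    """(B, L, E) sequence emitted by the CNN front-end."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("feature sequence must be (B, L, E)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature sequence contains non-finite values")

    @property
    def source_length(self) -> int:
        return self.values.shape[1]

    @property
    def embedding(self) -> int:
        return self.values.shape[2]


def output_length(n_samples: int, config: MultiScaleConfig) -> int:
    """Sequence length after both pooling stages: floor(floor(T/P1)/P2)."""
    return (n_samples // config.pool1) // config.pool2


def avg_pool(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping average pooling along the last axis (floor division)."""
    x = as_tensor(x)
    t = x.shape[-1]
    keep = (t // pool) * pool
    if keep == 0:
        raise ValueError(f"sequence of length {t} too short for pool size {pool}")
    x = x[..., :keep]
    return x.reshape(x.shape[:-1] + (t // pool, pool)).mean(axis=-1)


class MultiScaleBranch(nn.Module):
    """One temporal-scale branch of the front-end.

    temporal filterbank (1 x kernel, F1 filters, same padding)
    -> depthwise spatial conv (C, 1) with depth multiplier D
    -> BatchNorm + ELU -> avg-pool P1
    -> depthwise temporal refinement conv (1 x K2, same padding)
    -> BatchNorm + ELU -> avg-pool P2 -> dropout
    """

    def __init__(self, channels: int, kernel: int, config: MultiScaleConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.channels = channels
        self.kernel = int(kernel)
        self.config = config
        f1, d = config.f1, config.depth_multiplier
        self.temporal = nn.Parameter(rng.standard_normal((f1, kernel)) / np.sqrt(kernel))
        self.spatial = nn.Parameter(rng.standard_normal((f1, channels, d)) / np.sqrt(channels))
        self.bn1 = nn.BatchNorm(f1 * d)
        self.refine = nn.Parameter(
            rng.standard_normal((f1 * d, config.refine_kernel))
            / np.sqrt(config.refine_kernel)
        )
        self.bn2 = nn.BatchNorm(f1 * d)
        self.drop = nn.Dropout(config.dropout, rng=np.random.default_rng(rng.integers(2**31)))

    def forward(self, x):
        x = as_tensor(x)
        b, c, t = x.shape
        if c != self.channels:
            raise ValueError(f"input has {c} channels, branch built for {self.channels}")
        if t < self.kernel:
            raise ValueError(f"trial length {t} shorter than kernel {self.kernel}")
        f1, d = self.config.f1, self.config.depth_multiplier
        # The temporal filterbank and the depthwise spatial convolution are
        # linear maps acting on different axes, so they commute; applying
        # the spatial mix first shrinks the array the FFT convolution sees
        # (C channels -> F1*D maps) at identical output.
        # y[b,m,t] = sum_c mix[m,c] x[b,c,t] via broadcast matmul (1,M,C)@(B,C,T);
        # map index m = f*D + d matches the repeated temporal kernels below
        mix = self.spatial.transpose(0, 2, 1).reshape(1, f1 * d, c)
        h = mix @ x  # (B, F1*D, T)
        # temporal filter f applies to both depth maps of filter f
        kern = (
            self.temporal.reshape(f1, 1, self.kernel)
            * np.ones((1, d, 1), dtype=self.temporal.data.dtype)
        ).reshape(f1 * d, self.kernel)
        h = depthwise_time_conv(h, kern)  # (B, F1*D, T)
        h = avg_pool(elu(self.bn1(h)), self.config.pool1)
        h = depthwise_time_conv(h, self.refine)
        h = avg_pool(elu(self.bn2(h)), self.config.pool2)
        return self.drop(h)  # (B, F1*D, L)


class MPEBackbone(nn.Module):
    """Three branches plus 1x1 fusion into a (B, L, E) feature sequence."""

    def __init__(self, channels: int, config: MultiScaleConfig, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.config = config
        self.branches = [
            MultiScaleBranch(channels, k, config, rng=rng) for k in config.kernels
        ]
        self.fusion = nn.Linear(
            len(config.kernels) * config.branch_channels, config.embed_dim, rng=rng
        )

    def forward(self, x):
        outs = [branch(x) for branch in self.branches]
        h = outs[0] if len(outs) == 1 else concatenate(outs, axis=1)
        h = h.transpose(0, 2, 1)  # (B, L, n_branches*F1*D)
        return self.fusion(h)  # (B, L, E)


# ----------------------------------------------------------------------
# functional views (deterministic given seed), used for contract checks
# ----------------------------------------------------------------------
def branch_forward(
    dataset: EEGDataset,
    kernel: int,
    config: Optional[MultiScaleConfig] = None,
    *,
    branch: Optional[MultiScaleBranch] = None,
    seed: int = 0,
    training: bool = False,
) -> np.ndarray:
    """Run one temporal branch over a dataset, returning (B, F1*D, L)."""
    config = config or MultiScaleConfig()
    if kernel not in config.kernels:
        raise ValueError(f"kernel {kernel} not in configured triple {config.kernels}")
    if branch is None:
        branch = MultiScaleBranch(
            dataset.n_channels, kernel, config, rng=np.random.default_rng(seed)
        )
    branch.train(training)
    with no_grad():
        return branch(Tensor(dataset.trials)).data


def fuse_and_embed(
    branches,
    config: Optional[MultiScaleConfig] = None,
    *,
    fusion: Optional[nn.Linear] = None,
    seed: int = 0,
) -> FeatureSequence:
    """Concatenate three branch outputs and apply the 1x1 fusion conv."""
    config = config or MultiScaleConfig()
    arrays = [np.asarray(b, dtype=np.float64) for b in branches]
    if len(arrays) != 3 or any(a.shape != arrays[0].shape for a in arrays):
        raise ValueError("fuse_and_embed expects three identically shaped branch outputs")
    if fusion is None:
        fusion = nn.Linear(
            3 * config.branch_channels, config.embed_dim, rng=np.random.default_rng(seed)
        )
    with no_grad():
        h = np.concatenate(arrays, axis=1).transpose(0, 2, 1)
        out = fusion(Tensor(h)).data
    return FeatureSequence(out)
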