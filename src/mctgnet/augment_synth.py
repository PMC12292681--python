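"""Synthetic motor-imagery EEG and slice-and-recombine augmentation.

The generator emulates the statistical structure that MI decoders
exploit: every channel carries broadband Gaussian noise plus
band-limited mu (8–12 Hz) and beta (18–26 Hz) rhythms, and each class
attenuates mu-band power on its own contiguous block of channels — a
surrogate for event-related desynchronization (ERD) over the
class-specific sensorimotor area.  A second "session" (the test split)
receives small per-channel gain and offset perturbations, mimicking
cross-session distribution shift.  Everything is deterministic given the
seed.

Slice-and-recombine (S&R) augmentation cuts each trial into
``n_segments`` equal chronological segments (8 segments of 500 ms for
4-s trials at 250 Hz) and builds new same-class trials by drawing each
segment slot from a random donor trial of that class, preserving
chronological order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import signal

from .backbone import EEGDataset

__all__ = ["SynthConfig", "generate_synthetic_mi", "slice_and_recombine", "erd_channels"]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic MI generator."""

    channels: int = 22
    samples: int = 1000
    sampling_rate: float = 250.0
    classes: int = 4
    trials_per_class: int = 50
    test_trials_per_class: int = 25
    rhythm_bands: Tuple[Tuple[float, float], ...] = ((8.0, 12.0), (18.0, 26.0))
    rhythm_amplitude: float = 1.0
    erd_depth: float = 0.5
    noise_sigma: float = 1.0
    session_shift: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.channels < 1 or self.samples < 2 or self.classes < 1:
            raise ValueError("degenerate configuration: need channels, samples and classes")
        if self.trials_per_class < 1:
            raise ValueError("need at least one trial per class")
        nyquist = self.sampling_rate / 2.0
        for low, high in self.rhythm_bands:
            if not (0.0 < low < high < nyquist):
                raise ValueError(f"band ({low}, {high}) outside (0, {nyquist}) Hz")
        if not 0.0 <= self.erd_depth < 1.0:
            raise ValueError("erd_depth must lie in [0, 1)")
        if self.noise_sigma < 0 or self.session_shift < 0:
            raise ValueError("noise_sigma and session_shift must be nonnegative")


def erd_channels(config: SynthConfig, klass: int) -> np.ndarray:
    """Channels whose mu rhythm class ``klass`` desynchronizes.

    Contiguous blocks: class k owns channels [k*C//N, (k+1)*C//N)."""
    c, n = config.channels, config.classes
    return np.arange((klass * c) // n, ((klass + 1) * c) // n)


def _band_limited_noise(
    rng: np.random.Generator, shape: Tuple[int, ...], n: int, band, fs: float
) -> np.ndarray:
    """Unit-variance noise band-passed to ``band`` (zero-phase 4th-order IIR).

    Generates ``shape + (n,)`` independent rows in one vectorized call; 100
    samples of padding on each side absorb filter edge transients.
    """
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(shape + (n + 200,)), axis=-1)
    x = x[..., 100:-100]
    sd = x.std(axis=-1, keepdims=True)
    return x / np.where(sd > 0, sd, 1.0)


def _synth_split(
    config: SynthConfig, rng: np.random.Generator, per_class: int, shifted: bool
) -> EEGDataset:
    c, t, fs = config.channels, config.samples, config.sampling_rate
    n_trials = per_class * config.classes
    labels = np.repeat(np.arange(config.classes), per_class)
    mu_band = config.rhythm_bands[0]
    # session-level perturbation: one gain/offset vector per split
    if shifted and config.session_shift > 0:
        gain = 1.0 + config.session_shift * rng.standard_normal(c)
        offset = config.session_shift * rng.standard_normal(c)
    else:
        gain = np.ones(c)
        offset = np.zeros(c)
    erd_gain = np.sqrt(1.0 - config.erd_depth)  # power -> amplitude attenuation
    trials = config.noise_sigma * rng.standard_normal((n_trials, c, t))
    for band in config.rhythm_bands:
        amp = np.full((n_trials, c), config.rhythm_amplitude)
        if band == mu_band:
            for k in range(config.classes):
                rows = np.flatnonzero(labels == k)[:, None]
                amp[rows, erd_channels(config, k)[None, :]] *= erd_gain
        trials += amp[:, :, None] * _band_limited_noise(rng, (n_trials, c), t, band, fs)
    trials = trials * gain[None, :, None] + offset[None, :, None]
    return EEGDataset(trials, labels, sampling_rate=fs)


def generate_synthetic_mi(config: SynthConfig) -> Tuple[EEGDataset, EEGDataset]:
    """Generate (train, test) datasets; the test split carries the session shift."""
    rng = np.random.default_rng(config.seed)
    train = _synth_split(config, rng, config.trials_per_class, shifted=False)
    test = _synth_split(config, rng, config.test_trials_per_class, shifted=True)
    train.session_id, test.session_id = "session-1", "session-2"
    return train, test


def slice_and_recombine(
    dataset: EEGDataset, n_segments: int = 8, n_new: int = None, seed: int = 0
) -> EEGDataset:
    """Class-consistent segment recombination.

    Each synthetic trial keeps chronological order: its s-th segment is
    the s-th segment of a randomly chosen donor trial of the same class
    (donors drawn with replacement).  The source dataset is untouched.
    """
    t = dataset.n_samples
    if t % n_segments != 0:
        raise ValueError(f"trial length {t} not divisible by {n_segments} segments")
    if n_new is None:
        n_new = dataset.n_trials
    classes = np.unique(dataset.labels)
    by_class = {int(k): np.flatnonzero(dataset.labels == k) for k in classes}
    for k, idx in by_class.items():
        if idx.size == 0:
            raise ValueError(f"class {k} has no donor trials")
    rng = np.random.default_rng(seed)
    seg = t // n_segments
    new_labels = rng.choice(dataset.labels, size=n_new)  # class mix of the source
    new_trials = np.empty((n_new, dataset.n_channels, t))
    for i, y in enumerate(new_labels):
        donors = rng.choice(by_class[int(y)], size=n_segments)
        for s, d in enumerate(donors):
            new_trials[i, :, s * seg : (s + 1) * seg] = dataset.trials[
                d, :, s * seg : (s + 1) * seg
            ]
    return EEGDataset(
        new_trials, new_labels, dataset.sampling_rate, dataset.subject_id, dataset.session_id
    )
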