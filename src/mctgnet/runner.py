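"""Training / evaluation protocol, metrics, and data ingestion.

Subject-dependent protocol: for each subject, earlier-session trials
train the model and later-session trials test it; accuracy is reported
per subject and aggregated as mean +/- population standard deviation.

Training follows the fixed recipe: Adam with learning rate 0.001,
beta1 = 0.5, beta2 = 0.999, batch size 72, cross-entropy loss, optional
per-epoch slice-and-recombine augmentation of the training set.  No
learning-rate schedule, weight decay or early stopping; final-epoch
weights are used.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml
from sklearn.metrics import confusion_matrix as _sk_confusion

from .autodiff import Tensor, no_grad
from .backbone import EEGDataset
from .augment_synth import slice_and_recombine
from .model import MCTGNet, ModelConfig, cross_entropy_loss
from . import nn

__all__ = [
    "TrainConfig",
    "PreprocConfig",
    "Metrics",
    "train",
    "evaluate",
    "predict",
    "summarize_subjects",
    "load_gdf_session",
    "epochs_from_raw",
    "save_dataset",
    "load_dataset",
    "save_checkpoint",
    "load_checkpoint",
    "EVENT_MAP_IV2A",
    "EVENT_MAP_IV2B",
]

logger = logging.getLogger("mctgnet")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    beta1: float = 0.5
    beta2: float = 0.999
    epochs: int = 2000
    batch_size: int = 72
    seed: int = 0
    augmentation: bool = True
    augment_segments: int = 8
    dtype: str = "float32"  # training precision; weights are cast before fitting
    log_every: int = 0  # 0 = no per-epoch logging

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.epochs < 0:
            raise ValueError("batch_size must be >= 1 and epochs >= 0")


@dataclass
class Metrics:
    """Per-subject accuracy (percent), aggregate stats and confusion counts."""

    per_subject_accuracy: Dict[str, float]
    mean_accuracy: float
    std_accuracy: float
    confusion: np.ndarray

    def __post_init__(self):
        self.confusion = np.asarray(self.confusion, dtype=np.int64)
        if np.any(self.confusion < 0):
            raise ValueError("confusion counts must be nonnegative")
        for acc in self.per_subject_accuracy.values():
            if not 0.0 <= acc <= 100.0:
                raise ValueError("accuracy must lie in [0, 100]")


def _epoch_seed(base: int, epoch: int) -> int:
    return int(np.random.SeedSequence([base, epoch]).generate_state(1)[0] % (2**31))


def train(
    model_config: ModelConfig,
    train_config: TrainConfig,
    data: EEGDataset,
    model: Optional[MCTGNet] = None,
    on_step=None,
) -> Tuple[MCTGNet, List[float]]:
    """Train a decoder; returns the model and the per-epoch mean loss history."""
    if data.n_trials == 0:
        raise ValueError("training dataset is empty")
    if model is None:
        model = MCTGNet(model_config)
    dtype = np.dtype(train_config.dtype)
    model.astype(dtype)
    model.train()
    opt = nn.Adam(
        model.parameters(),
        lr=train_config.learning_rate,
        betas=(train_config.beta1, train_config.beta2),
    )
    rng = np.random.default_rng(train_config.seed)
    history: List[float] = []
    for epoch in range(train_config.epochs):
        if train_config.augmentation:
            aug = slice_and_recombine(
                data,
                n_segments=train_config.augment_segments,
                n_new=data.n_trials,
                seed=_epoch_seed(train_config.seed, epoch),
            )
            trials = np.concatenate([data.trials, aug.trials])
            labels = np.concatenate([data.labels, aug.labels])
        else:
            trials, labels = data.trials, data.labels
        order = rng.permutation(len(trials))
        losses = []
        for start in range(0, len(order), train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            model.zero_grad()
            logits = model(Tensor(trials[idx].astype(dtype)))
            loss = cross_entropy_loss(logits, labels[idx])
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"step {start // train_config.batch_size}"
                )
            loss.backward()
            opt.step()
            losses.append(value)
            if on_step is not None:
                on_step(epoch, len(losses) - 1, value)
        history.append(float(np.mean(losses)))
        if train_config.log_every and (epoch + 1) % train_config.log_every == 0:
            logger.info("epoch %d/%d loss %.4f", epoch + 1, train_config.epochs, history[-1])
    return model, history


def predict(model: MCTGNet, trials: np.ndarray, batch_size: int = 72) -> np.ndarray:
    """Class predictions in eval mode, batched to bound memory."""
    model.eval()
    out = []
    dtype = model.dtype
    with no_grad():
        for start in range(0, len(trials), batch_size):
            logits = model(Tensor(np.asarray(trials[start : start + batch_size], dtype=dtype)))
            out.append(logits.data.argmax(axis=1))
    return np.concatenate(out) if out else np.empty(0, dtype=np.int64)


def evaluate(model: MCTGNet, data: EEGDataset, batch_size: int = 72) -> Metrics:
    """Accuracy (percent) and confusion counts on one test dataset."""
    if data.n_trials == 0:
        raise ValueError("test dataset is empty")
    preds = predict(model, data.trials, batch_size=batch_size)
    acc = 100.0 * float(np.mean(preds == data.labels))
    n = model.config.classes
    conf = _sk_confusion(data.labels, preds, labels=np.arange(n))
    sid = data.subject_id or "subject-0"
    return Metrics({sid: acc}, mean_accuracy=acc, std_accuracy=0.0, confusion=conf)


def summarize_subjects(per_subject: Dict[str, float], confusion: Optional[np.ndarray] = None) -> Metrics:
    """Aggregate per-subject accuracies: mean and population std."""
    accs = np.array(list(per_subject.values()), dtype=np.float64)
    if accs.size == 0:
        raise ValueError("no subjects to aggregate")
    n = 1 if confusion is None else confusion.shape[0]
    conf = np.zeros((n, n), dtype=np.int64) if confusion is None else confusion
    return Metrics(
        dict(per_subject),
        mean_accuracy=float(accs.mean()),
        std_accuracy=float(accs.std()),  # population std (ddof=0)
        confusion=conf,
    )


# ----------------------------------------------------------------------
# GDF ingestion (real recordings; never required by the test suite)
# ----------------------------------------------------------------------
# standard annotation codes of the two competition montages
EVENT_MAP_IV2A = {"769": 0, "770": 1, "771": 2, "772": 3}  # left/right/feet/tongue
EVENT_MAP_IV2B = {"769": 0, "770": 1}  # left/right


@dataclass
class PreprocConfig:
    """Band-pass + notch + epoching settings applied to raw recordings."""

    l_freq: float = 0.5
    h_freq: float = 100.0
    notch: Optional[float] = 50.0
    tmin: float = 0.0  # seconds relative to the cue annotation
    duration: float = 4.0  # seconds of motor-relevant signal per trial
    event_map: Dict[str, int] = field(default_factory=lambda: dict(EVENT_MAP_IV2A))
    resample: bool = True  # resample to target_sfreq on mismatch (else reject)
    target_sfreq: float = 250.0


def epochs_from_raw(raw, preproc: PreprocConfig, subject_id=None, session_id=None) -> EEGDataset:
    """Filter, epoch and label an in-memory MNE Raw object."""
    import mne

    raw = raw.copy().pick("eeg")
    if raw.info["sfreq"] != preproc.target_sfreq:
        if not preproc.resample:
            raise ValueError(
                f"sampling rate {raw.info['sfreq']} Hz != required {preproc.target_sfreq} Hz"
            )
        raw.resample(preproc.target_sfreq)
    h = min(preproc.h_freq, preproc.target_sfreq / 2 - 1e-6)
    raw.filter(preproc.l_freq, h, method="iir",
               iir_params=dict(order=4, ftype="butter"), verbose="error")
    if preproc.notch and preproc.notch < preproc.target_sfreq / 2:
        raw.notch_filter(preproc.notch, method="iir", verbose="error")
    events, event_id = mne.events_from_annotations(raw, verbose="error")
    wanted = {k: v for k, v in event_id.items() if k in preproc.event_map}
    if not wanted:
        raise ValueError(
            f"no mapped events found; annotations present: {sorted(event_id)} "
            f"expected any of: {sorted(preproc.event_map)}"
        )
    n_samp = int(round(preproc.duration * preproc.target_sfreq))
    epochs = mne.Epochs(
        raw, events, event_id=wanted, tmin=preproc.tmin,
        tmax=preproc.tmin + (n_samp - 1) / preproc.target_sfreq,
        baseline=None, preload=True, verbose="error",
    )
    data = epochs.get_data(copy=True)[:, :, :n_samp] * 1e6  # volts -> microvolts
    code_by_id = {v: k for k, v in wanted.items()}
    labels = np.array([preproc.event_map[code_by_id[e]] for e in epochs.events[:, 2]])
    ds = EEGDataset(data, labels, sampling_rate=preproc.target_sfreq,
                    subject_id=subject_id, session_id=session_id)
    return ds


def load_gdf_session(path: str, preproc: Optional[PreprocConfig] = None, **kw) -> EEGDataset:
    """Read one GDF recording and return preprocessed C x 1000 epochs."""
    import mne

    preproc = preproc or PreprocConfig()
    try:
        raw = mne.io.read_raw_gdf(path, preload=True, verbose="error")
    except Exception as exc:  # pragma: no cover - depends on file contents
        raise ValueError(f"could not parse GDF file {path}: {exc}") from exc
    return epochs_from_raw(raw, preproc, **kw)


# ----------------------------------------------------------------------
# array container + checkpoints
# ----------------------------------------------------------------------
def save_dataset(path: str, dataset: EEGDataset) -> None:
    np.savez(
        path,
        trials=dataset.trials,
        labels=dataset.labels,
        sampling_rate=dataset.sampling_rate,
        subject_id=str(dataset.subject_id or ""),
        session_id=str(dataset.session_id or ""),
    )


def load_dataset(path: str) -> EEGDataset:
    with np.load(path, allow_pickle=False) as z:
        return EEGDataset(
            z["trials"],
            z["labels"],
            float(z["sampling_rate"]),
            str(z["subject_id"]) or None,
            str(z["session_id"]) or None,
        )


def _config_to_dict(config: ModelConfig) -> dict:
    b, e = config.backbone, config.encoder
    return {
        "channels": config.channels,
        "samples": config.samples,
        "classes": config.classes,
        "head_groups": config.head_groups,
        "standardize_input": config.standardize_input,
        "seed": config.seed,
        # backbone block mirrors the customary hyperparameter names
        "backbone": {
            "F1": b.f1, "D": b.depth_multiplier, "K1": list(b.kernels),
            "P1": b.pool1, "K2": b.refine_kernel, "P2": b.pool2,
            "E": b.embed_dim, "dropout": b.dropout,
        },
        "encoder": {
            "heads": e.heads, "local_kernels": list(e.local_kernels),
            "layers": e.layers, "dropout": e.dropout, "prenorm": e.prenorm,
            "mixer_expansion": e.mixer_expansion, "mixer_groups": e.mixer_groups,
        },
    }


def config_from_dict(d: dict) -> ModelConfig:
    from .backbone import MultiScaleConfig
    from .encoder import AttentionConfig

    b, e = d.get("backbone", {}), d.get("encoder", {})
    backbone = MultiScaleConfig(
        f1=b.get("F1", 8), depth_multiplier=b.get("D", 2),
        kernels=tuple(b.get("K1", (32, 64, 96))), pool1=b.get("P1", 8),
        refine_kernel=b.get("K2", 16), pool2=b.get("P2", 8),
        embed_dim=b.get("E", 16), dropout=b.get("dropout", 0.25),
    )
    encoder = AttentionConfig(
        embed_dim=b.get("E", 16), heads=e.get("heads", 4),
        local_kernels=tuple(e.get("local_kernels", (3, 5))),
        layers=e.get("layers", 1), dropout=e.get("dropout", 0.5),
        prenorm=e.get("prenorm", True),
        mixer_expansion=e.get("mixer_expansion", 4),
        mixer_groups=e.get("mixer_groups", 8),
    )
    return ModelConfig(
        channels=d.get("channels", 22), samples=d.get("samples", 1000),
        classes=d.get("classes", 4), backbone=backbone, encoder=encoder,
        head_groups=d.get("head_groups", 8),
        standardize_input=d.get("standardize_input", True),
        seed=d.get("seed", 0),
    )


def save_checkpoint(path: str, model: MCTGNet) -> None:
    """Single-file weight map keyed by module path, config embedded as YAML."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        yaml.safe_dump(_config_to_dict(model.config)).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path: str) -> MCTGNet:
    with np.load(path, allow_pickle=False) as z:
        cfg = yaml.safe_load(bytes(z["__config__"].tobytes()).decode())
        state = {k: z[k] for k in z.files if k != "__config__"}
    model = MCTGNet(config_from_dict(cfg))
    model.load_state_dict(state)
    return model
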