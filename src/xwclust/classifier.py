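"""Binary image classifier: the black-box contract the explanation pipeline needs.

A :class:`ClassifierHandle` exposes exactly two things about a model — a
pathology probability for an image and the penultimate-layer feature vector —
so every downstream step (occlusion attribution, explanation weighting,
clustering) is model-agnostic.

The default architecture, ``small_cnn``, is a compact convolutional network
(3 conv/pool blocks plus a final conv, global average pooling, single sigmoid
logit) sized to train in minutes on one CPU. A ``resnet50_transfer``
configuration mirroring the transfer-learning recipe (replace the head of an
ImageNet-pretrained 50-layer residual network with one neuron) is available
when torch/torchvision are installed.

Training follows the standard protocol for this task family: binary
cross-entropy, SGD with momentum 0.9, a step learning-rate schedule (decay
factor 0.1 every 7 epochs), and early stopping once the validation F1 score
fails to improve for 5 consecutive epochs.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import f1_score

from . import io as xio
from ._nn import SGDMomentum, SmallCNN, bce_with_logits, sigmoid
from .errors import DegenerateDataError, DimensionError, ParameterError
from .synthetic import DatasetManifest, augment


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Optimization protocol.

    ``lr=0.05`` and ``batch_size=16`` are sized for from-scratch training of
    the small CNN on desk-scale datasets of a few hundred images (the 0.001 /
    batch-64 recipe used when fine-tuning a large pretrained backbone gives a
    randomly initialized network far too few, and too small, updates per
    epoch); the remaining defaults follow the standard protocol: BCE loss,
    SGD momentum 0.9, step decay 0.1 every 7 epochs, early stop on validation
    F1 with patience 5.
    """

    batch_size: int = 16
    loss: str = "bce"
    optimizer: str = "sgd"
    lr: float = 0.05
    momentum: float = 0.9
    lr_decay_factor: float = 0.1
    lr_decay_period: int = 7
    early_stop_metric: str = "val_f1"
    patience: int = 5
    max_epochs: int = 30
    seed: int = 0
    augment: bool = True

    def __post_init__(self):
        if self.lr <= 0:
            raise ParameterError("learning rate must be > 0")
        if self.patience < 1:
            raise ParameterError("patience must be >= 1")
        if not 0.0 < self.lr_decay_factor <= 1.0:
            raise ParameterError("lr decay factor must be in (0, 1]")


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Learning rate in force at 1-indexed ``epoch`` under the step schedule."""
    return config.lr * config.lr_decay_factor ** ((epoch - 1) // config.lr_decay_period)


def run_early_stopping(
    epoch_fn: Callable[[int], float], max_epochs: int, patience: int
) -> tuple[list[float], int]:
    """Drive ``epoch_fn`` (0-indexed epoch -> monitored metric, higher better)
    until the metric fails to improve for ``patience`` consecutive epochs.

    Returns (metric history, best epoch index). The loop halts exactly
    ``patience`` epochs after the best epoch when the metric plateaus.
    """
    history: list[float] = []
    best = -np.inf
    best_epoch = -1
    since = 0
    for epoch in range(max_epochs):
        metric = epoch_fn(epoch)
        history.append(metric)
        if metric > best:
            best, best_epoch, since = metric, epoch, 0
        else:
            since += 1
        if since >= patience:
            break
    return history, best_epoch


class ClassifierHandle:
    """Opaque predictor: probability of the pathological class + penultimate
    features. Evaluation is pure (no dropout/batch-norm state), so repeated
    calls on the same image are identical."""

    def __init__(self, net: SmallCNN, history: list[dict] | None = None,
                 arch: str = "small_cnn", config: TrainConfig | None = None):
        self.net = net
        self.history = history or []
        self.arch = arch
        self.config = config

    @property
    def input_side(self) -> int:
        return self.net.input_side

    @property
    def feature_dim(self) -> int:
        return self.net.feature_dim

    def _check(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=np.float64)
        s = self.input_side
        if image.shape != (s, s, 3):
            raise DimensionError(
                f"expected image of shape ({s}, {s}, 3), got {image.shape}")
        return image

    def predict_proba(self, image: np.ndarray) -> float:
        logit, _ = self.net.forward(self._check(image)[None])
        return float(sigmoid(logit[0]))

    def predict_proba_many(self, images: Sequence[np.ndarray]) -> np.ndarray:
        batch = np.stack([self._check(im) for im in images])
        logits, _ = self.net.forward(batch)
        return sigmoid(logits)

    def features(self, image: np.ndarray) -> np.ndarray:
        _, feat = self.net.forward(self._check(image)[None])
        return feat[0]

    def features_many(self, images: Sequence[np.ndarray]) -> np.ndarray:
        batch = np.stack([self._check(im) for im in images])
        _, feats = self.net.forward(batch)
        return feats

    # -- persistence -------------------------------------------------------
    def save(self, model_dir: str | Path) -> None:
        model_dir = Path(model_dir)
        model_dir.mkdir(parents=True, exist_ok=True)
        np.savez(model_dir / "weights.npz", **self.net.state_dict())
        meta = dict(arch=self.arch, input_side=self.input_side,
                    channels=list(self.net.channels),
                    feature_dim=self.feature_dim, history=self.history,
                    config=dataclasses.asdict(self.config) if self.config else None)
        xio.save_json(model_dir / "model.json", meta)

    @classmethod
    def load(cls, model_dir: str | Path) -> "ClassifierHandle":
        model_dir = Path(model_dir)
        meta = xio.load_json(model_dir / "model.json")
        net = SmallCNN(input_side=meta["input_side"], channels=meta["channels"])
        with np.load(model_dir / "weights.npz") as state:
            net.load_state_dict(dict(state))
        config = TrainConfig(**meta["config"]) if meta.get("config") else None
        return cls(net, history=meta.get("history", []),
                   arch=meta.get("arch", "small_cnn"), config=config)


def _load_split(manifest: DatasetManifest, tag: str):
    rows = manifest.split(tag)
    images = np.stack([manifest.load_image(r) for _, r in rows.iterrows()])
    labels = (rows["label"] == "pathological").to_numpy(dtype=np.float64)
    return images, labels


def train_classifier(
    manifest: DatasetManifest,
    arch: str = "small_cnn",
    config: TrainConfig | None = None,
    channels: Sequence[int] = (8, 16, 32, 256),
) -> ClassifierHandle:
    """Train a binary healthy-vs-pathological classifier on the manifest's
    train split, early-stopped on the validation split's F1 score.

    Fully seeded: identical manifest + config reproduce the identical
    validation-metric trajectory and weights. The returned handle carries the
    best-epoch weights and a per-epoch history (lr, train loss, val F1).
    """
    if arch == "resnet50_transfer":
        raise ImportError(
            "resnet50_transfer requires the optional torch/torchvision "
            "dependencies (pip install xwclust[torch]); use arch='small_cnn' "
            "for a dependency-free model")
    if arch != "small_cnn":
        raise ParameterError(f"unknown architecture {arch!r}")
    config = config or TrainConfig()

    x_train, y_train = _load_split(manifest, "train")
    x_val, y_val = _load_split(manifest, "val")
    if len(np.unique(y_train)) < 2 or x_val.size == 0:
        raise DegenerateDataError(
            "training requires both classes in the train split and a non-empty "
            "validation split")

    side = x_train.shape[1]
    net = SmallCNN(input_side=side, channels=channels, seed=config.seed)
    opt = SGDMomentum(net.params(), lr=config.lr, momentum=config.momentum)
    rng = np.random.default_rng([config.seed, 0x7A])
    history: list[dict] = []
    best_state: dict | None = None

    def run_epoch(epoch: int) -> float:
        opt.lr = lr_at_epoch(config, epoch + 1)
        order = rng.permutation(len(x_train))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            batch = x_train[idx]
            if config.augment:
                batch = np.stack([
                    augment(im, rng_seed=[config.seed, epoch, int(j)])
                    for im, j in zip(batch, idx)])
            logits, _ = net.forward(batch, train=True)
            loss, dlogits = bce_with_logits(logits, y_train[idx])
            net.backward(dlogits)
            opt.step()
            losses.append(loss)
        val_logits, _ = net.forward(x_val)
        val_pred = (sigmoid(val_logits) >= 0.5).astype(int)
        val_f1 = float(f1_score(y_val.astype(int), val_pred, zero_division=0))
        history.append(dict(epoch=epoch + 1, lr=opt.lr,
                            train_loss=float(np.mean(losses)), val_f1=val_f1))
        return val_f1

    best = {"metric": -np.inf, "state": None}

    def run_epoch_snapshotting(epoch: int) -> float:
        metric = run_epoch(epoch)
        # strict >: keep the FIRST epoch reaching the best validation score.
        # Training past that point saturates the logit and collapses feature
        # diversity the clustering stage depends on.
        if metric > best["metric"]:
            best["metric"] = metric
            best["state"] = {k: v.copy() for k, v in net.state_dict().items()}
        return metric

    run_early_stopping(run_epoch_snapshotting, config.max_epochs, config.patience)

    if best["state"] is not None:  # restore best-epoch weights
        net.load_state_dict(best["state"])
    return ClassifierHandle(net, history=history, arch=arch, config=config)


def predict_proba(handle: ClassifierHandle, image: np.ndarray) -> float:
    """Probability of the pathological class; label = (p >= 0.5)."""
    return handle.predict_proba(image)


def extract_features(handle: ClassifierHandle, image: np.ndarray) -> np.ndarray:
    """Penultimate-layer (global-average-pool) feature vector."""
    return handle.features(image)
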