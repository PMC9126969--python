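"""Stratified splitting, the seeded training loop, and persistence.

Defaults follow the study conditions: 30 epochs, Adam (framework defaults),
categorical cross-entropy, an 80/20 stratified train/validation split, ReLU
activations (fixed in the architecture specs).  Batch size 32 is a package
choice.  All randomness — split shuffling, weight initialization, batch
shuffling, dropout masks — derives from the single ``seed`` field, so a run
is bit-reproducible.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from chirpnet import nn
from chirpnet.models import ModelSpec
from chirpnet.synthetic_audio import DatasetManifest

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 30
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    split_ratio: float = 0.8
    seed: int = 0
    loss: str = "categorical_crossentropy"

    def __post_init__(self) -> None:
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError(f"split_ratio must be in (0, 1), got {self.split_ratio}")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")

    def to_dict(self) -> dict:
        return {
            "epochs": self.epochs,
            "optimizer": self.optimizer,
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "split_ratio": self.split_ratio,
            "seed": self.seed,
            "loss": self.loss,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


@dataclass
class TrainHistory:
    """Per-epoch loss/accuracy on the training and validation sets."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.train_loss)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss", "train_acc", "val_loss", "val_acc"])
            for i in range(len(self)):
                writer.writerow(
                    [i + 1, self.train_loss[i], self.train_acc[i],
                     self.val_loss[i], self.val_acc[i]]
                )


def split_dataset(
    manifest: DatasetManifest, config: TrainConfig
) -> tuple[DatasetManifest, DatasetManifest]:
    """Stratified split: per class, floor(ratio·n) entries to train.

    Both sides keep at least one entry per class; the per-class shuffle is
    drawn from ``config.seed`` so the partition is deterministic.  The two
    manifests are disjoint and their union is the input.
    """
    labels = manifest.labels()
    counts = manifest.class_counts()
    small = np.flatnonzero(counts < 2)
    if small.size:
        raise ValueError(
            f"class {manifest.class_names[small[0]]} has {counts[small[0]]} "
            "entries; every class needs at least 2"
        )
    rng = np.random.default_rng(config.seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    for c in range(len(manifest.class_names)):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        n_train = int(np.floor(config.split_ratio * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1)
        train_idx.extend(idx[:n_train])
        val_idx.extend(idx[n_train:])
    train_idx.sort()
    val_idx.sort()
    mk = lambda ix: DatasetManifest(
        entries=[manifest.entries[i] for i in ix], class_names=list(manifest.class_names)
    )
    return mk(train_idx), mk(val_idx)


def load_images(manifest: DatasetManifest) -> tuple[np.ndarray, np.ndarray]:
    """Load the manifest's PNGs into (images, labels) arrays."""
    from chirpnet.wavelet import load_png

    images = np.stack([load_png(path) for path, _ in manifest.entries])
    return images.astype(np.float32), manifest.labels()


def _check_inputs(spec: ModelSpec, x: np.ndarray, y: np.ndarray, what: str) -> None:
    if x.shape[1:] != tuple(spec.input_shape):
        raise ValueError(
            f"{what} images have shape {x.shape[1:]}, spec expects {spec.input_shape}"
        )
    if y.min() < 0 or y.max() >= spec.n_classes:
        raise ValueError(f"{what} labels outside [0, {spec.n_classes})")


def _epoch_eval(net: nn.Network, x: np.ndarray, y: np.ndarray, batch_size: int) -> tuple[float, float]:
    losses, hits, seen = 0.0, 0, 0
    for start in range(0, x.shape[0], batch_size):
        xb, yb = x[start : start + batch_size], y[start : start + batch_size]
        logits = net.forward(xb, train=False)
        loss, _ = nn.softmax_cross_entropy(logits, yb)
        losses += loss * xb.shape[0]
        hits += int((logits.argmax(axis=1) == yb).sum())
        seen += xb.shape[0]
    return losses / seen, hits / seen


def train(
    spec: ModelSpec,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray] | None,
    config: TrainConfig,
) -> tuple[nn.Network, TrainHistory]:
    """Minimize categorical cross-entropy for exactly ``config.epochs`` epochs.

    Returns the trained network and the per-epoch history.  Validation data
    only ever flows through evaluation-mode forward passes; gradients are
    computed on training batches alone.
    """
    x_train = np.ascontiguousarray(np.asarray(train_data[0], dtype=np.float32))
    y_train = np.asarray(train_data[1], dtype=np.int64)
    _check_inputs(spec, x_train, y_train, "training")
    if val_data is not None:
        x_val = np.ascontiguousarray(np.asarray(val_data[0], dtype=np.float32))
        y_val = np.asarray(val_data[1], dtype=np.int64)
        _check_inputs(spec, x_val, y_val, "validation")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    net = nn.realize(spec, rng)
    opt = nn.Adam(net.params(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    history = TrainHistory()
    n = x_train.shape[0]
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        ep_loss, ep_hits = 0.0, 0
        for start in range(0, n, config.batch_size):
            sel = order[start : start + config.batch_size]
            xb, yb = x_train[sel], y_train[sel]
            logits = net.forward(xb, train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, yb)
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            ep_loss += loss * xb.shape[0]
            ep_hits += int((logits.argmax(axis=1) == yb).sum())
        history.train_loss.append(ep_loss / n)
        history.train_acc.append(ep_hits / n)
        if val_data is not None:
            vl, va = _epoch_eval(net, x_val, y_val, config.batch_size)
        else:
            vl, va = float("nan"), float("nan")
        history.val_loss.append(vl)
        history.val_acc.append(va)
        logger.info(
            "%s epoch %d/%d: loss %.4f acc %.3f val_loss %.4f val_acc %.3f",
            spec.name, epoch + 1, config.epochs,
            history.train_loss[-1], history.train_acc[-1], vl, va,
        )
    return net, history


def predict_proba(net: nn.Network, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
    """Class probabilities, one row per image; rows sum to 1."""
    images = np.asarray(images, dtype=np.float32)
    if images.shape[1:] != tuple(net.spec.input_shape):
        raise ValueError(
            f"images have shape {images.shape[1:]}, model expects {net.spec.input_shape}"
        )
    return net.predict_proba(images, batch_size=batch_size)


def save_checkpoint(net: nn.Network, weights_path, spec_path) -> None:
    """Model weights as .npz alongside the ModelSpec as JSON."""
    net.save(weights_path)
    net.spec.to_json(spec_path)


def load_checkpoint(weights_path, spec_path) -> nn.Network:
    spec = ModelSpec.from_json(spec_path)
    net = nn.realize(spec, np.random.default_rng(0))
    net.load(weights_path)
    return net


def with_seed(config: TrainConfig, seed: int) -> TrainConfig:
    return replace(config, seed=seed)
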