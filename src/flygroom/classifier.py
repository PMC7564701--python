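"""The behavior-detection CNN: architecture, training loop, inference.

The network maps a 100x100x3 feature image to a softmax over the seven
behavior classes.  It is deliberately small — three 3x3 convolution
blocks, each followed by 2x2 stride-2 max pooling with round-up output
sizes (100 -> 50 -> 25 -> 13), one fully connected layer, and a softmax
output — a few million parameters in total, orders of magnitude below a
VGG-class backbone.  Training follows the regime the feature images were
designed for: Adam at an initial learning rate of 0.01, categorical
cross-entropy, batch size 256, 10 epochs, with the best weights kept by
validation loss.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from . import nn
from .dataset import BEHAVIOR_CLASSES, LabelManifest
from .features import FeatureImage

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "FramePrediction",
    "Model",
    "build_model",
    "train",
    "predict",
    "load_model",
]

#: Inference/accumulation micro-batch size; bounds peak im2col memory.
_CHUNK = 64


def _pool_chain(size: int, n_pools: int) -> list[int]:
    sizes = [size]
    for _ in range(n_pools):
        sizes.append(math.ceil(sizes[-1] / 2))
    return sizes


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyper-parameters of the detection network."""

    input_size: int = 100
    conv_filters: tuple[int, int, int] = (32, 64, 128)
    dense_width: int = 128
    n_classes: int = len(BEHAVIOR_CLASSES)

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 3:
            raise ValueError("exactly three convolution blocks are supported")
        if min(self.conv_filters) < 1 or self.dense_width < 1 or self.n_classes < 2:
            raise ValueError("widths and class count must be positive")

    @property
    def feature_sizes(self) -> list[int]:
        """Spatial side lengths after each pooling stage (ceil-halving)."""
        return _pool_chain(self.input_size, 3)

    @property
    def flat_dim(self) -> int:
        return self.feature_sizes[-1] ** 2 * self.conv_filters[-1]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for :func:`train`."""

    learning_rate: float = 0.01
    batch_size: int = 256
    epochs: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass(frozen=True)
class FramePrediction:
    """Classifier output for the feature image of one frame."""

    window_index: int
    label: int                  #: argmax class id
    probabilities: np.ndarray   #: softmax over the 7 classes

    @property
    def behavior(self) -> str:
        return BEHAVIOR_CLASSES[self.label]


class Model:
    """A built (possibly trained) detection network."""

    def __init__(self, spec: ModelSpec, net: nn.Sequential):
        self.spec = spec
        self.net = net

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax probabilities for a batch of images in [0, 1], NHWC."""
        out = []
        for i in range(0, len(x), _CHUNK):
            logits = self.net.forward(x[i : i + _CHUNK].astype(np.float32))
            out.append(nn.softmax(logits.astype(np.float64)))
        return np.concatenate(out) if out else np.empty((0, self.spec.n_classes))

    def save(self, path: str | Path) -> None:
        spec = self.spec
        meta = {
            "input_size": spec.input_size,
            "conv_filters": list(spec.conv_filters),
            "dense_width": spec.dense_width,
            "n_classes": spec.n_classes,
        }
        weights = {f"w{i}": w for i, w in enumerate(self.net.get_weights())}
        np.savez_compressed(path, spec=json.dumps(meta), **weights)


def load_model(path: str | Path) -> Model:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["spec"]))
        weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
    spec = ModelSpec(
        input_size=meta["input_size"],
        conv_filters=tuple(meta["conv_filters"]),
        dense_width=meta["dense_width"],
        n_classes=meta["n_classes"],
    )
    model = build_model(spec, seed=0)
    model.net.set_weights(weights)
    return model


def build_model(spec: ModelSpec | None = None, seed: int = 0) -> Model:
    """Instantiate the network with Glorot-uniform-initialized weights.

    Two builds with the same seed produce identical initial weights.
    """
    if spec is None:
        spec = ModelSpec()
    rng = np.random.default_rng(seed)
    f1, f2, f3 = spec.conv_filters
    net = nn.Sequential(
        [
            nn.Conv3x3(rng, 3, f1),
            nn.ReLU(),
            nn.MaxPool2(),
            nn.Conv3x3(rng, f1, f2),
            nn.ReLU(),
            nn.MaxPool2(),
            nn.Conv3x3(rng, f2, f3),
            nn.ReLU(),
            nn.MaxPool2(),
            nn.Flatten(),
            nn.Dense(rng, spec.flat_dim, spec.dense_width),
            nn.ReLU(),
            nn.Dense(rng, spec.dense_width, spec.n_classes),
        ]
    )
    return Model(spec, net)


def _load_images(manifest: LabelManifest, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Load manifest images as float32 in [0, 1]; unreadable files are
    skipped with a warning."""
    xs, ys = [], []
    for path, label in manifest.records.itertuples(index=False):
        try:
            with Image.open(path) as im:
                arr = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
        except Exception as exc:
            logger.warning("skipping unreadable image %s: %s", path, exc)
            continue
        if arr.shape[:2] != (size, size):
            arr = (
                np.asarray(
                    Image.fromarray((arr * 255).astype(np.uint8)).resize(
                        (size, size), Image.BILINEAR
                    ),
                    dtype=np.float32,
                )
                / 255.0
            )
        xs.append(arr)
        ys.append(int(label))
    if not xs:
        raise ValueError("no readable images in manifest")
    return np.stack(xs), np.asarray(ys, dtype=np.int64)


def _evaluate(model: Model, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    probs = model.predict_proba(x)
    loss = float(-np.mean(np.log(probs[np.arange(len(y)), y] + 1e-12)))
    acc = float(np.mean(probs.argmax(axis=1) == y))
    return loss, acc


def train(
    model: Model,
    train_manifest: LabelManifest,
    val_manifest: LabelManifest,
    cfg: TrainConfig | None = None,
) -> "pd.DataFrame":
    """Train *model* in place; returns the per-epoch history.

    The history frame has columns ``epoch, train_loss, val_loss,
    train_acc, val_acc`` (training metrics are running averages over the
    epoch's batches, validation metrics are computed at epoch end).  The
    weights giving the lowest validation loss are restored before
    returning.
    """
    import pandas as pd

    if cfg is None:
        cfg = TrainConfig()
    x_train, y_train = _load_images(train_manifest, model.spec.input_size)
    x_val, y_val = _load_images(val_manifest, model.spec.input_size)
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(lr=cfg.learning_rate)
    best_loss, best_weights = np.inf, model.net.get_weights()
    rows = []
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(x_train))
        losses, hits, seen = [], 0, 0
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            model.net.zero_grad()
            batch_loss = 0.0
            # accumulate the batch gradient over memory-bounded chunks
            for c0 in range(0, len(batch), _CHUNK):
                idx = batch[c0 : c0 + _CHUNK]
                logits = model.net.forward(x_train[idx], train=True)
                loss, dlogits, probs = nn.softmax_cross_entropy(logits, y_train[idx])
                frac = len(idx) / len(batch)
                model.net.backward(dlogits * frac)
                batch_loss += loss * frac
                hits += int(np.sum(probs.argmax(axis=1) == y_train[idx]))
                seen += len(idx)
            opt.step(model.net.params)
            losses.append(batch_loss)
        val_loss, val_acc = _evaluate(model, x_val, y_val)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
                "train_acc": hits / seen,
                "val_acc": val_acc,
            }
        )
        logger.info(
            "epoch %d/%d: loss %.4f val_loss %.4f acc %.3f val_acc %.3f",
            epoch, cfg.epochs, rows[-1]["train_loss"], val_loss,
            rows[-1]["train_acc"], val_acc,
        )
        if val_loss < best_loss:
            best_loss = val_loss
            best_weights = model.net.get_weights()
    model.net.set_weights(best_weights)
    return pd.DataFrame(rows)


def predict(
    model: Model,
    images: Sequence[FeatureImage] | Iterable[FeatureImage],
) -> list[FramePrediction]:
    """One :class:`FramePrediction` per feature image, indices copied
    through."""
    images = list(images)
    if not images:
        return []
    preds: list[FramePrediction] = []
    for i in range(0, len(images), _CHUNK):
        chunk = images[i : i + _CHUNK]
        x = np.stack([im.pixels for im in chunk]).astype(np.float32) / 255.0
        probs = model.predict_proba(x)
        for im, p in zip(chunk, probs):
            preds.append(
                FramePrediction(
                    window_index=im.window_index,
                    label=int(np.argmax(p)),
                    probabilities=p,
                )
            )
    return preds
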