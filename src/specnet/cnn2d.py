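"""LeNet-5-style 2-D CNN on spectral images.

The classic LeNet-5 topology — two convolution+pooling stages (6 then 16
feature maps of 5x5 kernels, 2x2 pooling) followed by 120- and 84-unit fully
connected layers — with the output layer replaced by a K-way softmax head for
origin classification, ReLU activations and max pooling (the modern variant)
and seeded small-random-number initialisation.  Any input side from the
image-size study (26..40) is supported; the flatten size is recomputed from
the valid-convolution shape arithmetic.

After the full network is trained, the classifier head is re-initialised and
re-fit with the convolutional trunk frozen (``refit_head=True``), i.e. the
trunk's extracted features train a brand-new fully connected classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datasets import SpectraDataset
from .evaluation import EvalReport, evaluate
from .nn import (
    Conv2d,
    Dense,
    Dropout,
    Flatten,
    Network,
    Pool2d,
    ReLU,
    TrainSpec,
    TrainState,
    train,
)
from .spectral_image import SUPPORTED_SIDES, image_dataset

__all__ = [
    "LeNetConfig",
    "lenet_shape_trace",
    "build_lenet",
    "LeNetClassifier",
    "LeNetResults",
    "sweep_image_size",
]

logger = logging.getLogger("specnet.cnn2d")


@dataclass(frozen=True)
class LeNetConfig:
    """LeNet-5 variant: conv 6@5x5, pool 2x2, conv 16@5x5, pool 2x2, FC 120, FC 84."""

    input_side: int = 32
    conv1_maps: int = 6
    conv2_maps: int = 16
    kernel: int = 5
    pool: int = 2
    fc1: int = 120
    fc2: int = 84
    n_classes: int = 13
    dropout_p: float = 0.5

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        lenet_shape_trace(self)  # validates the spatial arithmetic


def lenet_shape_trace(cfg: LeNetConfig) -> list[tuple[str, int]]:
    """Spatial side length after each trunk layer; raises if any is non-positive."""
    side = cfg.input_side
    trace = [("input", side)]
    for stage in (1, 2):
        side = side - cfg.kernel + 1
        if side < 1:
            raise ValueError(
                f"input side {cfg.input_side} too small for conv stage {stage}"
            )
        trace.append((f"conv{stage}", side))
        side //= cfg.pool
        if side < 1:
            raise ValueError(
                f"input side {cfg.input_side} too small for pool stage {stage}"
            )
        trace.append((f"pool{stage}", side))
    return trace


def lenet_flatten_size(cfg: LeNetConfig) -> int:
    return cfg.conv2_maps * dict(lenet_shape_trace(cfg))["pool2"] ** 2


def build_lenet(cfg: LeNetConfig, seed: int = 0, dtype=np.float32) -> Network:
    """Instantiate the network; same seed gives byte-identical initial weights."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(202,)))
    flat = lenet_flatten_size(cfg)
    layers = [
        Conv2d(1, cfg.conv1_maps, cfg.kernel, cfg.kernel, rng, dtype=dtype),
        ReLU(),
        Pool2d(cfg.pool, mode="max"),
        Conv2d(cfg.conv1_maps, cfg.conv2_maps, cfg.kernel, cfg.kernel, rng, dtype=dtype),
        ReLU(),
        Pool2d(cfg.pool, mode="max"),
        Flatten(),
        Dense(flat, cfg.fc1, rng, dtype=dtype),
        ReLU(),
        Dropout(cfg.dropout_p, rng),
        Dense(cfg.fc1, cfg.fc2, rng, dtype=dtype),
        ReLU(),
        Dropout(cfg.dropout_p, rng),
        Dense(cfg.fc2, cfg.n_classes, rng, dtype=dtype),
    ]
    return Network(layers, config={"kind": "lenet", **cfg.__dict__})


class LeNetResults:
    """Results of a fitted 2-D CNN: history, head-refit state, evaluation."""

    def __init__(self, model, network: Network, state: TrainState,
                 scaler, head_state: TrainState | None = None):
        self.model = model
        self.network = network
        self.state = state
        self.head_state = head_state
        self._scaler = scaler

    @property
    def history(self) -> pd.DataFrame:
        return pd.DataFrame(self.state.history)

    def predict_images(self, images: np.ndarray, batch: int = 256) -> np.ndarray:
        X = self.model._prepare(np.asarray(images), self._scaler)
        out = [self.network.predict(X[i : i + batch]) for i in range(0, len(X), batch)]
        return np.concatenate(out)

    def evaluate(self, split: str = "test") -> EvalReport:
        ids = self.model.images
        mask = ids.split == split
        if not mask.any():
            raise ValueError(f"dataset has no {split!r} samples")
        pred = self.predict_images(ids.images[mask])
        return evaluate(ids.labels[mask], pred, ids.n_classes, class_names=ids.class_names)

    def accuracy(self, split: str = "test") -> float:
        return self.evaluate(split).accuracy

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "2-D CNN (LeNet-5 variant) classification results",
            "=" * 48,
            f"input image:      {cfg.input_side}*{cfg.input_side}",
            f"parameters:       {self.network.n_parameters():,}",
            f"epochs run:       {self.state.n_epochs} (best epoch {self.state.best_epoch})",
            f"head re-fit:      {self.head_state is not None}",
            f"train accuracy:   {self.accuracy('train'):.2f}%",
            f"test accuracy:    {self.accuracy('test'):.2f}%",
        ]
        return "\n".join(lines)


class LeNetClassifier:
    """2-D CNN origin classifier built from a preprocessed spectra dataset.

    The dataset's spectra are converted to ``input_side``-sided images
    (min-max scaled to [0, 1]) at construction.  For training, images are
    additionally standardised per pixel by the training split's statistics:
    each pixel is a fixed wavenumber, and quiet spectral regions carry class
    information that global scaling would leave numerically invisible.
    """

    def __init__(self, dataset: SpectraDataset, config: LeNetConfig | None = None):
        config = config or LeNetConfig(n_classes=dataset.n_classes)
        if config.n_classes != dataset.n_classes:
            raise ValueError("config n_classes does not match dataset classes")
        self.dataset = dataset
        self.config = config
        self.images = image_dataset(dataset, config.input_side)

    @classmethod
    def from_dataset(cls, dataset: SpectraDataset, **kwargs) -> "LeNetClassifier":
        return cls(dataset, LeNetConfig(n_classes=dataset.n_classes, **kwargs))

    @staticmethod
    def _prepare(images: np.ndarray, scaler: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
        mean, sd = scaler
        return ((images - mean) / sd)[:, None, :, :].astype(np.float32)

    def _split_for_fit(self, spec: TrainSpec, monitor: str, val_fraction: float):
        ids = self.images
        Xtr = ids.images[ids.split == "train"]
        ytr = ids.labels[ids.split == "train"]
        if monitor == "test":
            Xte = ids.images[ids.split == "test"]
            yte = ids.labels[ids.split == "test"]
            return (Xtr, ytr), (Xte, yte)
        if monitor != "val":
            raise ValueError("monitor must be 'val' or 'test'")
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(56,)))
        n = len(Xtr)
        n_val = max(1, int(round(val_fraction * n)))
        order = rng.permutation(n)
        val_idx, tr_idx = order[:n_val], order[n_val:]
        return (Xtr[tr_idx], ytr[tr_idx]), (Xtr[val_idx], ytr[val_idx])

    @staticmethod
    def _fit_scaler(images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mean = images.mean(axis=0)
        sd = images.std(axis=0)
        sd[sd == 0] = 1.0
        return mean, sd

    def fit(
        self,
        spec: TrainSpec = TrainSpec(),
        monitor: str = "val",
        val_fraction: float = 0.125,
        refit_head: bool = True,
        dtype=np.float32,
    ) -> LeNetResults:
        """Train the full network, then optionally re-fit a fresh head.

        With ``refit_head`` the trained convolutional trunk is frozen, the
        fully connected classifier is re-initialised from a fresh seed, and
        only the classifier is trained again on the trunk's features.
        """
        cfg = replace(self.config, dropout_p=spec.dropout_p)
        net = build_lenet(cfg, seed=spec.seed, dtype=dtype)
        (Xtr, ytr), (Xv, yv) = self._split_for_fit(spec, monitor, val_fraction)
        scaler = self._fit_scaler(Xtr)
        train_pair = (self._prepare(Xtr, scaler), ytr)
        val_pair = (self._prepare(Xv, scaler), yv)
        state = train(net, train_pair, val_pair, spec)

        head_state = None
        if refit_head:
            for layer in net.layers[:7]:  # conv/pool trunk + flatten
                layer.frozen = True
            head_rng = np.random.default_rng(
                np.random.SeedSequence(spec.seed, spawn_key=(203,))
            )
            flat = lenet_flatten_size(cfg)
            net.layers[7] = Dense(flat, cfg.fc1, head_rng, dtype=dtype)
            net.layers[10] = Dense(cfg.fc1, cfg.fc2, head_rng, dtype=dtype)
            net.layers[13] = Dense(cfg.fc2, cfg.n_classes, head_rng, dtype=dtype)
            head_state = train(net, train_pair, val_pair, spec)
        return LeNetResults(self, net, state, scaler, head_state=head_state)


def sweep_image_size(
    ds: SpectraDataset,
    sides: tuple[int, ...] = SUPPORTED_SIDES,
    spec: TrainSpec = TrainSpec(),
    refit_head: bool = False,
) -> pd.DataFrame:
    """Train one LeNet per image side; reports the retained wavenumber range."""
    rows = []
    sub_seeds = np.random.SeedSequence(spec.seed, spawn_key=(304,)).generate_state(
        len(sides)
    ) % (2**31)
    for side, sub in zip(sides, sub_seeds):
        cfg = LeNetConfig(input_side=side, n_classes=ds.n_classes)
        clf = LeNetClassifier(ds, cfg)
        res = clf.fit(replace(spec, seed=int(sub)), refit_head=refit_head)
        lo, hi = clf.images.wavenumber_range
        rows.append(
            {
                "image_size": f"{side}*{side}",
                "feature_range_cm-1": f"{lo:.0f}-{hi:.0f}",
                "test_accuracy": round(res.accuracy("test"), 2),
            }
        )
        logger.info("image side %d: test accuracy %.2f%%", side, rows[-1]["test_accuracy"])
    return pd.DataFrame(rows)
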