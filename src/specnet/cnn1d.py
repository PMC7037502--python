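"""The 1-D CNN architecture family for spectral classification.

A model of "depth" D = 2*n_stages + 3 stacks ``n_stages`` convolution+pooling
stages (the hidden feature extractor), then two equally sized fully connected
layers with ReLU and dropout, then a K-way softmax output layer.  Depth counts
hidden layers and the output layer, not the input: one stage gives depth 5,
two stages depth 7, and so on up to five stages (depth 13).  All stages share
one convolution kernel width, one pooling width and one feature-map count,
which is exactly the knob set the architecture sweeps vary.

``Cnn1dClassifier`` is the model object (built from a preprocessed
:class:`~specnet.datasets.SpectraDataset`); ``fit`` returns a
:class:`CnnResults` carrying the training history, the fitted network and
evaluation helpers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datasets import SpectraDataset
from .evaluation import EvalReport, evaluate
from .nn import (
    Conv1d,
    Dense,
    Dropout,
    Flatten,
    Network,
    Pool1d,
    ReLU,
    TrainSpec,
    TrainState,
    train,
)

__all__ = [
    "Cnn1dConfig",
    "shape_trace",
    "build_1d_model",
    "Cnn1dClassifier",
    "CnnResults",
    "sweep_depth",
    "sweep_kernel",
    "sweep_pool",
    "sweep_maps",
]

logger = logging.getLogger("specnet.cnn1d")


@dataclass(frozen=True)
class Cnn1dConfig:
    """One member of the 1-D CNN family.

    Defaults are the best-performing configuration found by the sweeps:
    4 stages (depth 11), convolution kernel 1*15, pooling kernel 1*2,
    24 feature maps per stage, 13 output classes on 1609-point spectra.
    """

    n_stages: int = 4
    conv_width: int = 15
    pool_width: int = 2
    feature_maps: int = 24
    n_classes: int = 13
    input_length: int = 1609
    pool_mode: str = "max"
    dropout_p: float = 0.5

    def __post_init__(self) -> None:
        if not 1 <= self.n_stages <= 5:
            raise ValueError("n_stages must be in 1..5")
        if self.conv_width < 1 or self.pool_width < 1:
            raise ValueError("kernel widths must be >= 1")
        if self.feature_maps < 1:
            raise ValueError("feature_maps must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        shape_trace(self, warn=False)  # validates length propagation

    @property
    def depth(self) -> int:
        """Network depth: hidden layers plus output layer (2*stages + 3)."""
        return 2 * self.n_stages + 3


def shape_trace(cfg: Cnn1dConfig, warn: bool = True) -> list[tuple[str, int]]:
    """Per-layer output lengths of the convolutional trunk.

    Convolution shortens a length-L input to L - m + 1; pooling divides by the
    pool width, discarding any trailing remainder (with a warning, since the
    preferred configurations divide exactly).  The first fully connected layer
    has ``final_length * feature_maps`` nodes.
    """
    trace: list[tuple[str, int]] = [("input", cfg.input_length)]
    length = cfg.input_length
    for stage in range(1, cfg.n_stages + 1):
        if length < cfg.conv_width:
            raise ValueError(
                f"stage {stage}: input length {length} shorter than "
                f"convolution kernel width {cfg.conv_width}"
            )
        length = length - cfg.conv_width + 1
        trace.append((f"conv{stage}", length))
        if length < cfg.pool_width:
            raise ValueError(
                f"stage {stage}: length {length} shorter than pool width {cfg.pool_width}"
            )
        if length % cfg.pool_width and warn:
            logger.warning(
                "stage %d: length %d not divisible by pool width %d; "
                "trailing remainder dropped", stage, length, cfg.pool_width,
            )
        length //= cfg.pool_width
        trace.append((f"pool{stage}", length))
    flat = length * cfg.feature_maps
    trace.append(("flatten", flat))
    trace.append(("fc1", flat))
    trace.append(("fc2", flat))
    trace.append(("output", cfg.n_classes))
    return trace


def fc1_size(cfg: Cnn1dConfig) -> int:
    return dict(shape_trace(cfg, warn=False))["fc1"]


def build_1d_model(cfg: Cnn1dConfig, seed: int = 0, dtype=np.float32) -> Network:
    """Instantiate the network with seeded small-random-number weights."""
    ss = np.random.SeedSequence(seed, spawn_key=(101,))
    rng = np.random.default_rng(ss)
    layers = []
    in_ch = 1
    for _ in range(cfg.n_stages):
        layers.append(Conv1d(in_ch, cfg.feature_maps, cfg.conv_width, rng, dtype=dtype))
        layers.append(ReLU())
        layers.append(Pool1d(cfg.pool_width, mode=cfg.pool_mode))
        in_ch = cfg.feature_maps
    flat = fc1_size(cfg)
    layers.append(Flatten())
    layers.append(Dense(flat, flat, rng, dtype=dtype))
    layers.append(ReLU())
    layers.append(Dropout(cfg.dropout_p, rng))
    layers.append(Dense(flat, flat, rng, dtype=dtype))
    layers.append(ReLU())
    layers.append(Dropout(cfg.dropout_p, rng))
    layers.append(Dense(flat, cfg.n_classes, rng, dtype=dtype))
    return Network(layers, config={"kind": "cnn1d", **cfg.__dict__})


class CnnResults:
    """Fitted-model results: training history, diagnostics, evaluation."""

    def __init__(self, model, network: Network, state: TrainState, scaler):
        self.model = model
        self.network = network
        self.state = state
        self._scaler = scaler

    @property
    def history(self) -> pd.DataFrame:
        return pd.DataFrame(self.state.history)

    def predict(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        """Predicted labels (1..K) for raw 2-D sample-by-feature input."""
        Xp = self.model._prepare(np.asarray(X, dtype=float), self._scaler)
        out = [self.network.predict(Xp[i : i + batch]) for i in range(0, len(Xp), batch)]
        return np.concatenate(out)

    def evaluate(self, split: str = "test") -> EvalReport:
        ds = self.model.dataset
        mask = ds.split == split
        if not mask.any():
            raise ValueError(f"dataset has no {split!r} samples")
        pred = self.predict(ds.absorbance[mask])
        return evaluate(ds.labels[mask], pred, ds.n_classes, class_names=ds.class_names)

    def accuracy(self, split: str = "test") -> float:
        return self.evaluate(split).accuracy

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "1-D CNN classification results",
            "=" * 34,
            f"depth:            {cfg.depth} ({cfg.n_stages} conv + {cfg.n_stages} pool stages)",
            f"conv kernel:      1*{cfg.conv_width}",
            f"pool kernel:      1*{cfg.pool_width} ({cfg.pool_mode})",
            f"feature maps:     {cfg.feature_maps}",
            f"parameters:       {self.network.n_parameters():,}",
            f"epochs run:       {self.state.n_epochs} (best epoch {self.state.best_epoch})",
            f"early stopped:    {self.state.stopped_early}",
            f"train accuracy:   {self.accuracy('train'):.2f}%",
            f"test accuracy:    {self.accuracy('test'):.2f}%",
        ]
        return "\n".join(lines)


class Cnn1dClassifier:
    """1-D CNN origin classifier built from a preprocessed spectra dataset.

    Inputs are standardised per wavenumber by the training split's column
    means and standard deviations (derivative spectra are numerically tiny
    and their scale varies strongly along the axis; per-column
    standardisation puts every spectral region on a scale where learning
    rate 0.01 is effective).
    """

    def __init__(self, dataset: SpectraDataset, config: Cnn1dConfig | None = None):
        config = config or Cnn1dConfig(
            n_classes=dataset.n_classes, input_length=dataset.grid.n_points
        )
        if config.input_length != dataset.grid.n_points:
            raise ValueError(
                f"config input_length {config.input_length} does not match "
                f"dataset spectra length {dataset.grid.n_points}"
            )
        if config.n_classes != dataset.n_classes:
            raise ValueError("config n_classes does not match dataset classes")
        self.dataset = dataset
        self.config = config

    @classmethod
    def from_dataset(cls, dataset: SpectraDataset, **kwargs) -> "Cnn1dClassifier":
        cfg = Cnn1dConfig(
            n_classes=dataset.n_classes, input_length=dataset.grid.n_points, **kwargs
        )
        return cls(dataset, cfg)

    @staticmethod
    def _prepare(X: np.ndarray, scaler: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
        mean, sd = scaler
        Xs = (X - mean) / sd
        return Xs[:, None, :].astype(np.float32)

    def _split_for_fit(
        self, spec: TrainSpec, monitor: str, val_fraction: float
    ) -> tuple[tuple, tuple]:
        Xtr = self.dataset.absorbance[self.dataset.split == "train"]
        ytr = self.dataset.labels[self.dataset.split == "train"]
        if monitor == "test":
            Xte = self.dataset.absorbance[self.dataset.split == "test"]
            yte = self.dataset.labels[self.dataset.split == "test"]
            return (Xtr, ytr), (Xte, yte)
        if monitor != "val":
            raise ValueError("monitor must be 'val' or 'test'")
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(55,)))
        n = len(Xtr)
        n_val = max(1, int(round(val_fraction * n)))
        order = rng.permutation(n)
        val_idx, tr_idx = order[:n_val], order[n_val:]
        return (Xtr[tr_idx], ytr[tr_idx]), (Xtr[val_idx], ytr[val_idx])

    def fit(
        self,
        spec: TrainSpec = TrainSpec(),
        monitor: str = "val",
        val_fraction: float = 0.125,
        dtype=np.float32,
    ) -> CnnResults:
        """Train with mini-batch SGD and early stopping; returns results.

        ``monitor='val'`` (default) carves a validation subset out of the
        training split for early stopping; ``monitor='test'`` monitors the
        test split, replicating protocols that stop on test error directly.
        """
        cfg = replace(self.config, dropout_p=spec.dropout_p)
        net = build_1d_model(cfg, seed=spec.seed, dtype=dtype)
        (Xtr, ytr), (Xv, yv) = self._split_for_fit(spec, monitor, val_fraction)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        scaler = (Xtr.mean(axis=0), sd)
        state = train(
            net,
            (self._prepare(Xtr, scaler), ytr),
            (self._prepare(Xv, scaler), yv),
            spec,
        )
        return CnnResults(self, net, state, scaler)


def _run_one(
    ds: SpectraDataset, cfg: Cnn1dConfig, spec: TrainSpec, sub_seed: int
) -> CnnResults:
    spec = replace(spec, seed=sub_seed)
    return Cnn1dClassifier(ds, cfg).fit(spec)


def _sweep(
    ds: SpectraDataset,
    configs: list[tuple[str, Cnn1dConfig]],
    spec: TrainSpec,
    varied: str,
    values: list,
) -> pd.DataFrame:
    rows = []
    base = np.random.SeedSequence(spec.seed, spawn_key=(303,))
    sub_seeds = base.generate_state(len(configs)) % (2**31)
    for (name, cfg), value, sub in zip(configs, values, sub_seeds):
        res = _run_one(ds, cfg, spec, int(sub))
        rows.append(
            {
                "model": name,
                varied: value,
                "depth": cfg.depth,
                "train_accuracy": round(res.accuracy("train"), 2),
                "test_accuracy": round(res.accuracy("test"), 2),
            }
        )
        logger.info("sweep %s=%s: test accuracy %.2f%%", varied, value, rows[-1]["test_accuracy"])
    return pd.DataFrame(rows)


def sweep_depth(
    ds: SpectraDataset,
    depths: tuple[int, ...] = (5, 7, 9, 11, 13),
    base_cfg: Cnn1dConfig | None = None,
    spec: TrainSpec = TrainSpec(),
) -> pd.DataFrame:
    """Train one model per depth; depth D uses (D - 3) / 2 stages.

    The depth study's base settings are convolution kernel 1*5, pooling 1*2,
    12 feature maps per stage.
    """
    base_cfg = base_cfg or Cnn1dConfig(
        n_stages=1, conv_width=5, pool_width=2, feature_maps=12,
        n_classes=ds.n_classes, input_length=ds.grid.n_points,
    )
    configs = []
    for d in depths:
        if (d - 3) % 2 or not 1 <= (d - 3) // 2 <= 5:
            raise ValueError(f"unsupported depth {d}; must be one of 5,7,9,11,13")
        cfg = replace(base_cfg, n_stages=(d - 3) // 2)
        configs.append((f"1D_CNN_{d}", cfg))
    return _sweep(ds, configs, spec, "depth_varied", list(depths))


def sweep_kernel(
    ds: SpectraDataset,
    widths: tuple[int, ...] = (3, 5, 7, 9, 11, 13, 15, 17, 19, 21),
    base_cfg: Cnn1dConfig | None = None,
    spec: TrainSpec = TrainSpec(),
) -> pd.DataFrame:
    """Vary the convolution kernel width at fixed depth (default 11)."""
    base_cfg = base_cfg or Cnn1dConfig(
        n_stages=4, conv_width=3, pool_width=2, feature_maps=12,
        n_classes=ds.n_classes, input_length=ds.grid.n_points,
    )
    configs = [(f"conv_1x{w}", replace(base_cfg, conv_width=w)) for w in widths]
    return _sweep(ds, configs, spec, "conv_width", list(widths))


def sweep_pool(
    ds: SpectraDataset,
    widths: tuple[int, ...] = (1, 2, 3, 4, 5),
    base_cfg: Cnn1dConfig | None = None,
    spec: TrainSpec = TrainSpec(),
) -> pd.DataFrame:
    """Vary the pooling (sampling) kernel width; width 1 is identity pooling."""
    base_cfg = base_cfg or Cnn1dConfig(
        n_stages=4, conv_width=15, pool_width=1, feature_maps=12,
        n_classes=ds.n_classes, input_length=ds.grid.n_points,
    )
    configs = [(f"pool_1x{w}", replace(base_cfg, pool_width=w)) for w in widths]
    return _sweep(ds, configs, spec, "pool_width", list(widths))


def sweep_maps(
    ds: SpectraDataset,
    counts: tuple[int, ...] = (6, 12, 18, 24, 30, 36),
    base_cfg: Cnn1dConfig | None = None,
    spec: TrainSpec = TrainSpec(),
) -> pd.DataFrame:
    """Vary the per-stage feature-map count at fixed depth (default 11)."""
    base_cfg = base_cfg or Cnn1dConfig(
        n_stages=4, conv_width=15, pool_width=2, feature_maps=6,
        n_classes=ds.n_classes, input_length=ds.grid.n_points,
    )
    configs = [(f"maps_{m}", replace(base_cfg, feature_maps=m)) for m in counts]
    return _sweep(ds, configs, spec, "feature_maps", list(counts))
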