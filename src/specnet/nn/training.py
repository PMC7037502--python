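"""Mini-batch SGD training with early stopping.

The protocol: plain gradient descent (no momentum), learning rate 0.01,
batch size 40, at most 50 epochs, cross-entropy loss, dropout p = 0.5 active
on fully connected layers during training only.  A held-out set is monitored
every epoch; when its error has not improved for ``early_stop_patience``
epochs, training stops and the weights of the best epoch seen are restored.
Monitoring a carved-out validation split avoids test-set leakage; monitoring
the test split directly is available for protocol-faithful replication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .network import Network, softmax_cross_entropy

__all__ = ["TrainSpec", "TrainState", "train"]

logger = logging.getLogger("specnet.train")


@dataclass(frozen=True)
class TrainSpec:
    """Optimisation hyperparameters (defaults follow the study protocol)."""

    learning_rate: float = 0.01
    batch_size: int = 40
    max_epochs: int = 50
    dropout_p: float = 0.5
    early_stop_patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if not 0.0 <= self.dropout_p < 1.0:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.early_stop_patience < 1:
            raise ValueError("early_stop_patience must be >= 1")


@dataclass
class TrainState:
    """Outcome of a training run: final weights live in the network itself."""

    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_error: float = float("inf")
    best_state: list[np.ndarray] | None = None
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.history)


def _error_rate(net: Network, X: np.ndarray, y: np.ndarray, batch: int = 256) -> float:
    wrong = 0
    for i in range(0, len(X), batch):
        pred = net.predict(X[i : i + batch])
        wrong += int(np.sum(pred != y[i : i + batch]))
    return wrong / len(X)


def train(
    net: Network,
    train_set: tuple[np.ndarray, np.ndarray],
    val_set: tuple[np.ndarray, np.ndarray],
    spec: TrainSpec = TrainSpec(),
) -> TrainState:
    """Train ``net`` in place; returns the state with per-epoch history.

    ``train_set`` / ``val_set`` are ``(X, labels)`` pairs with labels in 1..K.
    The network is left holding the best-epoch weights (minimum validation
    error; ties keep the earliest epoch).
    """
    X, y = train_set
    Xv, yv = val_set
    if len(X) == 0 or len(Xv) == 0:
        raise ValueError("training and validation sets must be non-empty")
    if len(X) != len(y) or len(Xv) != len(yv):
        raise ValueError("data/label length mismatch")

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(17,)))
    state = TrainState()
    since_best = 0

    for epoch in range(spec.max_epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), spec.batch_size):
            idx = order[start : start + spec.batch_size]
            logits = net.forward(X[idx], training=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1}; "
                    "reduce the learning rate or check the input scaling"
                )
            net.backward(dlogits.astype(logits.dtype))
            for p, g in zip(net.parameters(), net.gradients()):
                p -= spec.learning_rate * g
            losses.append(loss)

        train_err = _error_rate(net, X, y)
        val_err = _error_rate(net, Xv, yv)
        state.history.append(
            {
                "epoch": epoch + 1,
                "train_loss": float(np.mean(losses)),
                "train_error": train_err,
                "val_error": val_err,
            }
        )
        logger.info(
            "epoch %d/%d loss=%.4f train_err=%.4f val_err=%.4f",
            epoch + 1, spec.max_epochs, np.mean(losses), train_err, val_err,
        )

        if val_err < state.best_val_error:
            state.best_val_error = val_err
            state.best_epoch = epoch + 1
            state.best_state = net.get_state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= spec.early_stop_patience:
                state.stopped_early = True
                logger.info(
                    "early stop at epoch %d (no improvement for %d epochs)",
                    epoch + 1, spec.early_stop_patience,
                )
                break

    if state.best_state is not None:
        net.set_state(state.best_state)
    return state
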