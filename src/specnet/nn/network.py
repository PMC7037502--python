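"""Sequential network container, softmax cross-entropy loss, checkpoints."""

from __future__ import annotations

import copy
import json

import numpy as np

from .layers import Layer, softmax

__all__ = ["Network", "softmax_cross_entropy", "save_checkpoint", "load_checkpoint"]


class Network:
    """A plain stack of layers producing class scores (logits).

    ``forward`` returns logits; ``predict_proba`` applies softmax.  In
    evaluation mode (``training=False``) dropout is inert, so repeated calls
    on the same input are identical.
    """

    def __init__(self, layers: list[Layer], config: dict | None = None):
        self.layers = layers
        self.config = dict(config or {})

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for i, layer in enumerate(self.layers):
            try:
                x = layer.forward(x, training=training)
            except ValueError as exc:
                raise ValueError(
                    f"layer {i} ({type(layer).__name__}): {exc}"
                ) from exc
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False), axis=1)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predicted labels in 1..K (argmax of the class probabilities)."""
        return np.argmax(self.forward(x, training=False), axis=1) + 1

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers if not layer.frozen for p in layer.params]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers if not layer.frozen for g in layer.grads]

    def all_parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.all_parameters()))

    def get_state(self) -> list[np.ndarray]:
        return [p.copy() for p in self.all_parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.all_parameters()
        if len(state) != len(params):
            raise ValueError("checkpoint state does not match network structure")
        for p, s in zip(params, state):
            if p.shape != s.shape:
                raise ValueError(f"shape mismatch {p.shape} vs {s.shape}")
            p[...] = s

    def clone_structure(self) -> "Network":
        return copy.deepcopy(self)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of softmax(logits) against labels in 1..K.

    Returns ``(loss, dlogits)`` where ``dlogits`` is the gradient of the mean
    loss, i.e. ``(probs - onehot) / batch``.
    """
    n = logits.shape[0]
    probs = softmax(logits, axis=1)
    idx = np.asarray(labels, dtype=int) - 1
    if idx.min() < 0 or idx.max() >= logits.shape[1]:
        raise ValueError("labels outside 1..K")
    eps = np.finfo(probs.dtype).tiny
    loss = float(-np.mean(np.log(probs[np.arange(n), idx] + eps)))
    dlogits = probs.copy()
    dlogits[np.arange(n), idx] -= 1.0
    return loss, dlogits / n


CHECKPOINT_VERSION = 1


def save_checkpoint(net: Network, path) -> None:
    """Single-file checkpoint: versioned arrays plus the config as JSON."""
    arrays = {f"param_{i}": p for i, p in enumerate(net.all_parameters())}
    meta = json.dumps({"version": CHECKPOINT_VERSION, "config": net.config})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_checkpoint(net: Network, path) -> dict:
    """Restore weights into a structurally matching network; returns the config."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version: {meta.get('version')}")
        n = len([k for k in data.files if k.startswith("param_")])
        net.set_state([data[f"param_{i}"] for i in range(n)])
    return meta["config"]
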