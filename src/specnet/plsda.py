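"""PLS-DA baseline classifier and 2-D embedding views (PCA / t-SNE).

PLS-DA regresses the (mean-centred) spectra onto a one-hot class-indicator
matrix with a small number of latent variables (default 7) and assigns each
sample to the class whose fitted indicator response is largest, ties broken
toward the lower class index.  It is the standard linear chemometric
benchmark the CNN models are compared against, fit on the same preprocessed
feature segment used for the 32 x 32 spectral image (the first 1024 points,
4000 up to roughly 7740 cm^-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .datasets import SpectraDataset
from .evaluation import EvalReport, evaluate

__all__ = [
    "PlsdaModel",
    "fit_plsda",
    "predict_plsda",
    "PlsdaClassifier",
    "PlsdaResults",
    "embed_2d",
]

logger = logging.getLogger("specnet.plsda")


@dataclass
class PlsdaModel:
    """Fitted PLS2 regression onto the class-indicator matrix."""

    regression: PLSRegression
    n_components: int
    n_classes: int
    n_features: int

    @property
    def x_weights(self) -> np.ndarray:
        return self.regression.x_weights_

    @property
    def coefficients(self) -> np.ndarray:
        return self.regression.coef_


def fit_plsda(X: np.ndarray, labels: np.ndarray, n_components: int = 7) -> PlsdaModel:
    """Fit PLS-DA: PLS2 of X on the one-hot indicator matrix of the labels."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one label per row")
    classes = np.unique(y)
    if classes.min() < 1:
        raise ValueError("labels must be in 1..K")
    n_classes = int(classes.max())
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    max_comp = min(len(X) - 1, X.shape[1])
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must be in 1..{max_comp} "
            f"(n_samples-1={len(X) - 1}, n_features={X.shape[1]})"
        )
    Y = np.zeros((len(y), n_classes))
    Y[np.arange(len(y)), y - 1] = 1.0
    reg = PLSRegression(n_components=n_components, scale=False, tol=1e-12, max_iter=2000)
    reg.fit(X, Y)
    return PlsdaModel(
        regression=reg,
        n_components=n_components,
        n_classes=n_classes,
        n_features=X.shape[1],
    )


def predict_plsda(model: PlsdaModel, X: np.ndarray) -> np.ndarray:
    """Labels in 1..K: argmax over fitted indicator responses (ties -> lower index)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1] if X.ndim == 2 else X.shape}"
        )
    scores = model.regression.predict(X)
    return np.argmax(scores, axis=1) + 1  # np.argmax keeps the first (lowest) maximum


class PlsdaResults:
    """Fitted PLS-DA baseline with dataset-level evaluation helpers."""

    def __init__(self, model_obj, pls: PlsdaModel):
        self.model = model_obj
        self.pls = pls

    def predict(self, X: np.ndarray) -> np.ndarray:
        return predict_plsda(self.pls, np.asarray(X)[:, : self.pls.n_features])

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
        return "\n".join(
            [
                "PLS-DA classification results",
                "=" * 30,
                f"latent variables: {self.pls.n_components}",
                f"feature segment:  first {self.pls.n_features} points",
                f"train accuracy:   {self.accuracy('train'):.2f}%",
                f"test accuracy:    {self.accuracy('test'):.2f}%",
            ]
        )


class PlsdaClassifier:
    """PLS-DA model object over a preprocessed spectra dataset.

    ``n_features`` selects the low-wavenumber feature segment (default the
    first 1024 points, matching the 32 x 32 image study).
    """

    def __init__(
        self,
        dataset: SpectraDataset,
        n_components: int = 7,
        n_features: int = 1024,
    ):
        if n_features > dataset.grid.n_points:
            raise ValueError("n_features exceeds spectrum length")
        self.dataset = dataset
        self.n_components = n_components
        self.n_features = n_features

    def fit(self) -> PlsdaResults:
        mask = self.dataset.split == "train"
        X = self.dataset.absorbance[mask][:, : self.n_features]
        pls = fit_plsda(X, self.dataset.labels[mask], self.n_components)
        return PlsdaResults(self, pls)


def embed_2d(
    X: np.ndarray,
    method: str = "pca",
    seed: int = 0,
    perplexity: float = 30.0,
) -> tuple[np.ndarray, np.ndarray | None]:
    """2-D view of a spectra matrix for class-separability inspection.

    Returns ``(coords, explained_variance_fractions)``; the variance
    fractions are PCA-only (None for t-SNE).  t-SNE runs seeded with
    PCA initialisation, 1000 iterations.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(X) < 3:
        raise ValueError("embedding needs a 2-D matrix with >= 3 samples")
    if method == "pca":
        if np.allclose(X, X[0]):
            raise ValueError("constant matrix: explained variance undefined")
        pca = PCA(n_components=2, random_state=seed)
        coords = pca.fit_transform(X)
        return coords, pca.explained_variance_ratio_
    if method == "tsne":
        perplexity = min(perplexity, (len(X) - 1) / 3.0)
        tsne = TSNE(
            n_components=2,
            perplexity=perplexity,
            max_iter=1000,
            init="pca",
            random_state=seed,
        )
        return tsne.fit_transform(X), None
    raise ValueError(f"unknown embedding method {method!r}")


def embedding_frame(coords: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(
        {"dim1": coords[:, 0], "dim2": coords[:, 1], "label": np.asarray(labels, int)}
    )
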