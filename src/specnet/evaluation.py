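"""Classification accuracy, confusion matrices, and the model-comparison driver.

Accuracy is reported in percent: P_A = 100 * N_C / N_T, where N_C is the
number of correctly classified samples and N_T the total.  Confusion matrices
are K x K integer counts, rows = true class, columns = predicted class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

__all__ = ["EvalReport", "evaluate", "compare_models"]


@dataclass
class EvalReport:
    """Accuracy and confusion-matrix report for one model on one label set."""

    accuracy: float
    n_correct: int
    n_total: int
    confusion: np.ndarray
    per_class_accuracy: np.ndarray
    class_names: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "n_correct": self.n_correct,
            "n_total": self.n_total,
            "confusion": self.confusion.tolist(),
            "per_class_accuracy": self.per_class_accuracy.tolist(),
            "class_names": list(self.class_names),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(
            accuracy=float(d["accuracy"]),
            n_correct=int(d["n_correct"]),
            n_total=int(d["n_total"]),
            confusion=np.asarray(d["confusion"], dtype=int),
            per_class_accuracy=np.asarray(d["per_class_accuracy"], dtype=float),
            class_names=list(d.get("class_names", [])),
        )

    def confusion_frame(self) -> pd.DataFrame:
        names = self.class_names or [str(i + 1) for i in range(self.confusion.shape[0])]
        return pd.DataFrame(self.confusion, index=names, columns=names)


def evaluate(
    true_labels: np.ndarray,
    predicted_labels: np.ndarray,
    n_classes: int,
    class_names: list[str] | None = None,
) -> EvalReport:
    """Score predictions against truth; labels are integers in 1..K."""
    y = np.asarray(true_labels, dtype=int)
    p = np.asarray(predicted_labels, dtype=int)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("label vectors must be 1-D and equal length")
    if y.size == 0:
        raise ValueError("empty label vectors")
    for name, v in (("true", y), ("predicted", p)):
        if v.min() < 1 or v.max() > n_classes:
            raise ValueError(f"{name} labels outside 1..{n_classes}")
    conf = confusion_matrix(y, p, labels=np.arange(1, n_classes + 1))
    n_correct = int(np.trace(conf))
    n_total = int(y.size)
    row_tot = conf.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row_tot > 0, 100.0 * np.diag(conf) / row_tot, np.nan)
    return EvalReport(
        accuracy=100.0 * n_correct / n_total,
        n_correct=n_correct,
        n_total=n_total,
        confusion=conf,
        per_class_accuracy=per_class,
        class_names=list(class_names or [f"C{i}" for i in range(1, n_classes + 1)]),
    )


def compare_models(
    ds,
    cnn1d_config=None,
    lenet_config=None,
    plsda_components: int = 7,
    train_spec=None,
    feature_side: int = 32,
) -> dict:
    """Fit and score the three classifiers on one preprocessed dataset.

    Trains the 1-D CNN on the full spectra, the LeNet on ``feature_side``-sided
    spectral images, and PLS-DA on the feature-segment matrix (the same first
    ``feature_side**2`` points), all from the train split under one shared
    seed, then evaluates each on the test split.  Returns
    ``{"table": DataFrame, "reports": {name: EvalReport}, "results": {...}}``.
    """
    from .cnn1d import Cnn1dClassifier, Cnn1dConfig
    from .cnn2d import LeNetClassifier, LeNetConfig
    from .nn import TrainSpec
    from .plsda import PlsdaClassifier

    spec = train_spec or TrainSpec()
    cfg1 = cnn1d_config or Cnn1dConfig(
        n_classes=ds.n_classes, input_length=ds.grid.n_points
    )
    cfg2 = lenet_config or LeNetConfig(input_side=feature_side, n_classes=ds.n_classes)

    res_1d = Cnn1dClassifier(ds, cfg1).fit(spec)
    res_2d = LeNetClassifier(ds, cfg2).fit(spec)
    res_pls = PlsdaClassifier(
        ds, n_components=plsda_components, n_features=feature_side**2
    ).fit()

    reports = {
        "1D_CNN": res_1d.evaluate("test"),
        "2D_LeNet-5": res_2d.evaluate("test"),
        "PLS_DA": res_pls.evaluate("test"),
    }
    params = {
        "1D_CNN": f"C: 1*{cfg1.conv_width}; S: 1*{cfg1.pool_width}; M={cfg1.feature_maps}",
        "2D_LeNet-5": f"input size: {cfg2.input_side}*{cfg2.input_side}",
        "PLS_DA": f"feature segment ({feature_side**2} points); components: {plsda_components}",
    }
    table = pd.DataFrame(
        [
            {
                "model": name,
                "main_parameters": params[name],
                "test_accuracy": round(rep.accuracy, 2),
            }
            for name, rep in reports.items()
        ]
    )
    return {
        "table": table,
        "reports": reports,
        "results": {"1D_CNN": res_1d, "2D_LeNet-5": res_2d, "PLS_DA": res_pls},
    }
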