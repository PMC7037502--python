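"""Dataset / report serialisation and run configuration.

Datasets travel as plain CSV: one sample per row, columns
``wavenumber_1 .. wavenumber_n, label, split``, with a JSON sidecar
(``<stem>.meta.json``) recording the generator configuration and the grid
endpoints for provenance.  Evaluation reports are JSON.  Run configurations
are YAML with unknown keys rejected.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import SpectraDataset, WavenumberGrid, default_grid
from .evaluation import EvalReport

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_report",
    "read_report",
    "RunConfig",
    "load_run_config",
    "setup_logging",
]

logger = logging.getLogger("specnet.io")


class ParseError(ValueError):
    """Malformed dataset or report file."""


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_dataset(ds: SpectraDataset, path, config: dict | None = None) -> None:
    """Write CSV (full float precision, round-trips exactly) plus JSON sidecar."""
    path = Path(path)
    n = ds.grid.n_points
    frame = pd.DataFrame(
        ds.absorbance, columns=[f"wavenumber_{i}" for i in range(1, n + 1)]
    )
    frame["label"] = ds.labels
    frame["split"] = ds.split
    frame.to_csv(path, index=False)
    meta = {
        "grid": {
            "start": float(ds.grid.values[0]),
            "stop": float(ds.grid.values[-1]),
            "n_points": n,
        },
        "class_names": list(ds.class_names),
        "config": config or {},
    }
    _sidecar(path).write_text(json.dumps(meta, indent=2))


def read_dataset(path, expected_grid: WavenumberGrid | None = None) -> SpectraDataset:
    """Read a dataset written by :func:`write_dataset`.

    ``expected_grid`` (optional) enforces the spectrum length; otherwise the
    grid is taken from the sidecar, falling back to the default 4000-10000
    span over the column count.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty file") from exc
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if frame.empty:
        raise ParseError(f"{path}: no data rows")
    for col in ("label", "split"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    spec_cols = [c for c in frame.columns if c.startswith("wavenumber_")]
    n = len(spec_cols)
    if n < 2:
        raise ParseError(f"{path}: found {n} wavenumber columns, need >= 2")

    if expected_grid is not None:
        if n != expected_grid.n_points:
            raise ParseError(
                f"{path}: {n} absorbance columns but expected grid has "
                f"{expected_grid.n_points} points"
            )
        grid = expected_grid
    else:
        meta_path = _sidecar(path)
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            g = meta["grid"]
            if g["n_points"] != n:
                raise ParseError(
                    f"{path}: sidecar grid has {g['n_points']} points, file has {n}"
                )
            grid = WavenumberGrid(np.linspace(g["start"], g["stop"], n))
        else:
            grid = default_grid(n)

    absorbance = (
        frame[spec_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    )
    bad = ~np.isfinite(absorbance).all(axis=1)
    if bad.any():
        raise ParseError(
            f"{path}: non-numeric or non-finite absorbance in row {int(np.argmax(bad)) + 1}"
        )
    try:
        labels = frame["label"].to_numpy(dtype=int)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-integer label column: {exc}") from exc

    class_names: list[str] = []
    meta_path = _sidecar(path)
    if meta_path.exists():
        class_names = json.loads(meta_path.read_text()).get("class_names", [])
    k = len(class_names) or int(labels.max())
    out_of_range = (labels < 1) | (labels > k)
    if out_of_range.any():
        raise ParseError(
            f"{path}: label outside 1..{k} in row {int(np.argmax(out_of_range)) + 1}"
        )
    try:
        return SpectraDataset(
            absorbance, labels, frame["split"].to_numpy(), grid, class_names
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_report(report: EvalReport, path) -> None:
    """JSON report: accuracy, counts, row-major confusion matrix, per-class accuracy."""
    d = report.to_dict()
    if not np.isfinite(d["accuracy"]):
        raise ValueError("report accuracy is not finite")
    Path(path).write_text(json.dumps(d, indent=2))


def read_report(path) -> EvalReport:
    try:
        return EvalReport.from_dict(json.loads(Path(path).read_text()))
    except (json.JSONDecodeError, KeyError) as exc:
        raise ParseError(f"{path}: malformed report: {exc}") from exc


_RUN_CONFIG_KEYS = {
    "data", "output_dir", "seed",
    "preprocess", "sg_window", "sg_polyorder", "sg_deriv",
    "model", "n_stages", "conv_width", "pool_width", "feature_maps",
    "image_side", "plsda_components",
    "learning_rate", "batch_size", "max_epochs", "dropout_p", "early_stop_patience",
}


@dataclass
class RunConfig:
    """Whole-run configuration; one top-level seed feeds every module."""

    data: str
    output_dir: str = "runs"
    seed: int = 0
    preprocess: bool = True
    sg_window: int = 9
    sg_polyorder: int = 3
    sg_deriv: int = 1
    model: str = "cnn1d"
    n_stages: int = 4
    conv_width: int = 15
    pool_width: int = 2
    feature_maps: int = 24
    image_side: int = 32
    plsda_components: int = 7
    learning_rate: float = 0.01
    batch_size: int = 40
    max_epochs: int = 50
    dropout_p: float = 0.5
    early_stop_patience: int = 5

    def __post_init__(self) -> None:
        if not Path(self.data).exists():
            raise FileNotFoundError(f"data path does not exist: {self.data}")


def load_run_config(path) -> RunConfig:
    """Load a YAML run config, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: run config must be a YAML mapping")
    unknown = set(raw) - _RUN_CONFIG_KEYS
    if unknown:
        raise ParseError(f"{path}: unknown config keys: {sorted(unknown)}")
    if "data" not in raw:
        raise ParseError(f"{path}: missing required key 'data'")
    return RunConfig(**raw)


def setup_logging(level: int = logging.INFO) -> None:
    """Structured logging to stderr (per-epoch training lines at INFO)."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("specnet")
    root.handlers[:] = [handler]
    root.setLevel(level)
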