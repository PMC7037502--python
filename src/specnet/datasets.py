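"""Spectra containers and the synthetic NIR spectra generator.

Real flue-cured tobacco NIR spectra are proprietary, so the package ships a
generator that emulates the study design they came from: 13 origin classes
(C1..C13), 400 samples per class with a fixed 320/80 train/test split, spectra
on a 4000-10000 cm^-1 wavenumber grid of 1609 points, each sample the average
of 3 replicate scans.  Spectra are built from Gaussian absorption bands --
some shared by every origin, some specific to a class -- plus a smooth
baseline, per-sample baseline drift (slope + offset) and white noise, which
reproduces the qualitative structure of diffuse-reflectance NIR data: broad
overlapping bands on a drifting baseline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WavenumberGrid",
    "SpectraDataset",
    "SynthConfig",
    "class_template",
    "generate_dataset",
    "default_grid",
]

#: default spectral axis: 1609 points spanning 4000-10000 cm^-1
GRID_START = 4000.0
GRID_STOP = 10000.0
GRID_POINTS = 1609

# namespaces for per-purpose RNG streams derived from one seed
_NS_CLASS = 1
_NS_SHARED = 2
_NS_SAMPLES = 3


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly increasing wavenumber axis in cm^-1, from 4000 to 10000."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("wavenumber grid needs at least 2 points")
        if not np.all(np.diff(values) > 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        if not (values[0] == GRID_START and values[-1] == GRID_STOP):
            raise ValueError(
                f"grid must span {GRID_START:.0f}..{GRID_STOP:.0f} cm^-1, "
                f"got {values[0]:.6g}..{values[-1]:.6g}"
            )

    @property
    def n_points(self) -> int:
        return int(self.values.size)

    @property
    def spacing(self) -> float:
        """Uniform grid spacing in cm^-1."""
        return float((self.values[-1] - self.values[0]) / (self.values.size - 1))


def default_grid(n_points: int = GRID_POINTS) -> WavenumberGrid:
    """Uniform grid of ``n_points`` over 4000-10000 cm^-1 (default 1609)."""
    return WavenumberGrid(np.linspace(GRID_START, GRID_STOP, n_points))


@dataclass
class SpectraDataset:
    """Sample x wavenumber absorbance matrix with labels and split tags.

    ``labels`` are integers in 1..K; ``split`` holds ``"train"`` / ``"test"``
    per sample.
    """

    absorbance: np.ndarray
    labels: np.ndarray
    split: np.ndarray
    grid: WavenumberGrid
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.split = np.asarray(self.split, dtype=object)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        n = self.absorbance.shape[0]
        if self.labels.shape != (n,) or self.split.shape != (n,):
            raise ValueError("labels/split length must match sample count")
        if self.absorbance.shape[1] != self.grid.n_points:
            raise ValueError(
                f"spectrum length {self.absorbance.shape[1]} does not match "
                f"grid length {self.grid.n_points}"
            )
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        if n and (self.labels.min() < 1):
            raise ValueError("labels must be in 1..K")
        bad = set(np.unique(self.split)) - {"train", "test"}
        if bad:
            raise ValueError(f"unknown split tags: {sorted(bad)}")
        if not self.class_names:
            k = int(self.labels.max()) if n else 0
            self.class_names = [f"C{i}" for i in range(1, k + 1)]
        if n and self.labels.max() > len(self.class_names):
            raise ValueError("labels exceed class_names length")

    @property
    def n_samples(self) -> int:
        return int(self.absorbance.shape[0])

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def subset(self, mask: np.ndarray) -> "SpectraDataset":
        return SpectraDataset(
            self.absorbance[mask],
            self.labels[mask],
            self.split[mask],
            self.grid,
            list(self.class_names),
        )

    def train_test(self) -> tuple["SpectraDataset", "SpectraDataset"]:
        return self.subset(self.split == "train"), self.subset(self.split == "test")


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic-spectra generator.

    Defaults reproduce the emulated study design: 13 origins x 400 samples,
    320 train / 80 test per origin, 3 replicate scans averaged per sample.
    ``separability`` scales the class-specific band amplitudes (0 makes every
    class template identical); ``band_sign_flip`` multiplies each sample's
    class-specific component by an alternating +-1 (half the class each way),
    so class identity is carried by band *positions* rather than mean
    intensity -- a nonlinear structure that defeats linear classifiers while
    remaining learnable by ReLU networks.
    """

    n_classes: int = 13
    samples_per_class: int = 400
    train_per_class: int = 320
    n_replicates: int = 3
    n_points: int = GRID_POINTS
    bands_per_class: int = 4
    band_amplitude_range: tuple[float, float] = (0.05, 0.30)
    band_width_range: tuple[float, float] = (60.0, 250.0)
    shared_band_count: int = 6
    shared_amplitude_range: tuple[float, float] = (0.2, 1.0)
    baseline_slope_sd: float = 0.05
    baseline_offset_sd: float = 0.05
    noise_sd: float = 0.01
    separability: float = 1.0
    band_sign_flip: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1 or self.samples_per_class < 1:
            raise ValueError("class and per-class sample counts must be positive")
        if not (0 < self.train_per_class < self.samples_per_class):
            raise ValueError("train_per_class must be in 1..samples_per_class-1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for name in ("baseline_slope_sd", "baseline_offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.separability < 0:
            raise ValueError("separability must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _rng(seed: int, namespace: int, *key: int) -> np.random.Generator:
    """Independent generator derived from one top-level seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(namespace, *key)))


def _gaussian_bands(
    grid: np.ndarray,
    centers: np.ndarray,
    widths: np.ndarray,
    amplitudes: np.ndarray,
) -> np.ndarray:
    x = grid[None, :]
    g = amplitudes[:, None] * np.exp(-0.5 * ((x - centers[:, None]) / widths[:, None]) ** 2)
    return g.sum(axis=0)


def _shared_component(cfg: SynthConfig, grid: np.ndarray) -> np.ndarray:
    """Bands common to every origin plus a smooth global baseline."""
    rng = _rng(cfg.seed, _NS_SHARED)
    lo, hi = grid[0], grid[-1]
    centers = rng.uniform(lo + 200.0, hi - 200.0, size=cfg.shared_band_count)
    widths = rng.uniform(*cfg.band_width_range, size=cfg.shared_band_count)
    amps = rng.uniform(*cfg.shared_amplitude_range, size=cfg.shared_band_count)
    shared = _gaussian_bands(grid, centers, widths, amps)
    # gentle curved baseline common to all classes (absorbance rises toward
    # the low-wavenumber end in diffuse-reflectance NIR)
    t = (grid - lo) / (hi - lo)
    baseline = 0.3 * (1.0 - t) + 0.1 * (1.0 - t) ** 2
    return shared + baseline


def _class_band_params(
    class_id: int, cfg: SynthConfig, grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    # per-class stream keyed by class id: adding classes never perturbs
    # the band parameters of earlier classes
    rng = _rng(cfg.seed, _NS_CLASS, class_id)
    lo, hi = grid[0], grid[-1]
    centers = rng.uniform(lo + 100.0, hi - 100.0, size=cfg.bands_per_class)
    widths = rng.uniform(*cfg.band_width_range, size=cfg.bands_per_class)
    amps = rng.uniform(*cfg.band_amplitude_range, size=cfg.bands_per_class)
    return centers, widths, amps


def class_template(
    class_id: int, cfg: SynthConfig, grid: WavenumberGrid | None = None
) -> np.ndarray:
    """Noise-free mean spectrum of one origin class.

    shared bands + baseline + separability-scaled class-specific bands.
    With ``separability == 0`` every class collapses onto the shared template.
    """
    if not 1 <= class_id <= cfg.n_classes:
        raise ValueError(f"class_id {class_id} outside 1..{cfg.n_classes}")
    g = (grid or default_grid(cfg.n_points)).values
    template = _shared_component(cfg, g)
    if cfg.separability > 0:
        centers, widths, amps = _class_band_params(class_id, cfg, g)
        template = template + cfg.separability * _gaussian_bands(g, centers, widths, amps)
    return template


def _class_component(class_id: int, cfg: SynthConfig, g: np.ndarray) -> np.ndarray:
    centers, widths, amps = _class_band_params(class_id, cfg, g)
    return cfg.separability * _gaussian_bands(g, centers, widths, amps)


def generate_dataset(cfg: SynthConfig) -> SpectraDataset:
    """Generate the full labeled dataset defined by ``cfg``.

    Each sample is the arithmetic mean of ``n_replicates`` replicate scans
    sharing one per-sample baseline drift (linear in wavenumber) and
    differing by i.i.d. additive Gaussian noise.  The first
    ``train_per_class`` samples of each class are tagged ``train``, the rest
    ``test``.  Byte-identical output under a fixed seed.
    """
    grid = default_grid(cfg.n_points)
    g = grid.values
    n_total = cfg.n_classes * cfg.samples_per_class
    X = np.empty((n_total, cfg.n_points))
    labels = np.empty(n_total, dtype=int)
    split = np.empty(n_total, dtype=object)
    shared = _shared_component(cfg, g)
    t_centered = (g - g[0]) / (g[-1] - g[0]) - 0.5

    row = 0
    for k in range(1, cfg.n_classes + 1):
        class_part = _class_component(k, cfg, g) if cfg.separability > 0 else 0.0
        rng = _rng(cfg.seed, _NS_SAMPLES, k)
        for j in range(cfg.samples_per_class):
            slope = rng.normal(0.0, cfg.baseline_slope_sd)
            offset = rng.normal(0.0, cfg.baseline_offset_sd)
            # alternate signs so each class is exactly balanced: class means
            # coincide and only the band *positions* identify the class
            sign = (1.0 if j % 2 == 0 else -1.0) if cfg.band_sign_flip else 1.0
            clean = shared + sign * class_part + slope * t_centered + offset
            reps = clean[None, :] + rng.normal(
                0.0, cfg.noise_sd, size=(cfg.n_replicates, cfg.n_points)
            ) if cfg.noise_sd > 0 else np.broadcast_to(clean, (cfg.n_replicates, cfg.n_points))
            X[row] = reps.mean(axis=0)
            labels[row] = k
            split[row] = "train" if j < cfg.train_per_class else "test"
            row += 1

    class_names = [f"C{i}" for i in range(1, cfg.n_classes + 1)]
    return SpectraDataset(X, labels, split, grid, class_names)
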