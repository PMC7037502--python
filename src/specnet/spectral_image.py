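"""Conversion of 1-D spectra into square 2-D images by row-major reshaping.

A spectrum prefix of n*n points is cut into n consecutive subvectors of
length n and stacked as the rows of an n x n matrix: points 1..n become row
one, points n+1..2n row two, and so on.  On the 1609-point grid the full
spectrum gives a 40 x 40 image (the last 9 points are dropped); the
high-signal feature segment of the first 1024 points (4000 up to roughly
7740 cm^-1) gives a 32 x 32 image.  Shrinking the side length in steps of 2
truncates the spectrum further from the high-wavenumber end — the spectral
axis is ascending, so "the right side" of the spectrum is the noisy
high-wavenumber tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datasets import SpectraDataset, WavenumberGrid

__all__ = [
    "SpectralImage",
    "ImageDataset",
    "vector_to_image",
    "feature_segment_image",
    "image_dataset",
    "save_image_png",
    "SUPPORTED_SIDES",
]

logger = logging.getLogger("specnet.spectral_image")

#: side lengths of the image-size study, 40*40 down to 26*26 in steps of 2
SUPPORTED_SIDES = (40, 38, 36, 34, 32, 30, 28, 26)


@dataclass(frozen=True)
class SpectralImage:
    """Square image holding the first n*n points of a spectrum, row-major."""

    pixels: np.ndarray
    side: int
    source_range: tuple[int, int]  # [first, last] 0-based indices consumed
    wavenumber_range: tuple[float, float] | None = None

    def flatten(self) -> np.ndarray:
        """Inverse of the reshape: the consumed spectrum prefix."""
        return self.pixels.reshape(-1)


def vector_to_image(spectrum: np.ndarray, side: int) -> SpectralImage:
    """Reshape the first side**2 points row-major; surplus points dropped."""
    spectrum = np.asarray(spectrum, dtype=float).reshape(-1)
    n2 = side * side
    if side < 1:
        raise ValueError("side must be >= 1")
    if n2 > spectrum.size:
        raise ValueError(
            f"spectrum has {spectrum.size} points, fewer than {side}*{side}={n2}"
        )
    pixels = spectrum[:n2].reshape(side, side)
    return SpectralImage(pixels=pixels, side=side, source_range=(0, n2 - 1))


def feature_segment_image(
    spectrum: np.ndarray, grid: WavenumberGrid, side: int
) -> SpectralImage:
    """Image of the low-wavenumber feature segment (first side**2 points).

    The retained wavenumber range is read off the grid (it starts at
    4000 cm^-1 and ends where the consumed prefix ends); sides outside the
    studied 26..40 even set are allowed but warned about.
    """
    if side not in SUPPORTED_SIDES:
        logger.warning("image side %d outside the studied set %s", side, SUPPORTED_SIDES)
    img = vector_to_image(spectrum, side)
    lo, hi = img.source_range
    if hi >= grid.n_points:
        raise ValueError("grid shorter than the consumed prefix")
    return SpectralImage(
        pixels=img.pixels,
        side=side,
        source_range=img.source_range,
        wavenumber_range=(float(grid.values[lo]), float(grid.values[hi])),
    )


@dataclass
class ImageDataset:
    """Stack of spectral images with the labels/split of the source dataset."""

    images: np.ndarray  # (n_samples, side, side)
    labels: np.ndarray
    split: np.ndarray
    side: int
    wavenumber_range: tuple[float, float]
    class_names: list[str]

    @property
    def n_samples(self) -> int:
        return int(self.images.shape[0])

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


def save_image_png(image: SpectralImage, path) -> None:
    """Export one spectral image as a grayscale PNG for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(image.pixels, cmap="gray", interpolation="nearest")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def image_dataset(ds: SpectraDataset, side: int, scale: bool = True) -> ImageDataset:
    """Convert every sample of a (preprocessed) dataset into an image.

    With ``scale=True`` pixel values are min-max scaled to [0, 1] using the
    dataset-wide extremes of the consumed prefix, the usual normalisation for
    image-network input.  Labels and split tags carry over unchanged.
    """
    n2 = side * side
    if n2 > ds.grid.n_points:
        raise ValueError(
            f"spectra have {ds.grid.n_points} points, fewer than {side}*{side}"
        )
    prefix = ds.absorbance[:, :n2]
    if scale:
        lo, hi = prefix.min(), prefix.max()
        prefix = (prefix - lo) / (hi - lo) if hi > lo else np.zeros_like(prefix)
    images = prefix.reshape(ds.n_samples, side, side)
    return ImageDataset(
        images=images,
        labels=ds.labels.copy(),
        split=ds.split.copy(),
        side=side,
        wavenumber_range=(float(ds.grid.values[0]), float(ds.grid.values[n2 - 1])),
        class_names=list(ds.class_names),
    )
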