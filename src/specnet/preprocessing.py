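"""Savitzky-Golay first-derivative preprocessing.

Raw diffuse-reflectance NIR spectra carry baseline drift and high-frequency
noise that swamp the chemically informative band shapes.  The standard
chemometric remedy applied here is a joint first derivative + Savitzky-Golay
smoothing: a local least-squares polynomial (window 9 points, order 3) is fit
around every point and its analytic first derivative evaluated at the centre.
The derivative is taken with respect to wavenumber (units absorbance*cm), so
results are grid-spacing aware.  Constant baseline offsets vanish exactly and
linear drift becomes a constant, which the downstream classifiers ignore.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .datasets import SpectraDataset, WavenumberGrid

__all__ = ["SgParams", "sg_derivative", "preprocess_dataset"]


@dataclass(frozen=True)
class SgParams:
    """Savitzky-Golay filter parameters (defaults: window 9, order 3, 1st deriv)."""

    window: int = 9
    polyorder: int = 3
    deriv_order: int = 1

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError(f"window must be an odd integer >= 3, got {self.window}")
        if self.polyorder < 1:
            raise ValueError("polyorder must be >= 1")
        if self.polyorder >= self.window:
            raise ValueError(
                f"polyorder ({self.polyorder}) must be smaller than window ({self.window})"
            )
        if not 0 <= self.deriv_order <= self.polyorder:
            raise ValueError("deriv_order must be in 0..polyorder")


def sg_derivative(
    spectrum: np.ndarray,
    grid: WavenumberGrid,
    params: SgParams = SgParams(),
) -> np.ndarray:
    """S-G smoothed derivative of one spectrum (or a stack, rows = spectra).

    Output has the input's length: at the boundaries the local polynomial is
    fit on the one-sided window and differentiated there, so no values outside
    the measured 4000-10000 cm^-1 range are fabricated.  Exact for polynomial
    signals up to ``polyorder``.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape[-1] != grid.n_points:
        raise ValueError(
            f"spectrum length {spectrum.shape[-1]} does not match grid "
            f"length {grid.n_points}"
        )
    if spectrum.shape[-1] < params.window:
        raise ValueError(
            f"spectrum length {spectrum.shape[-1]} shorter than window {params.window}"
        )
    out = savgol_filter(
        spectrum,
        window_length=params.window,
        polyorder=params.polyorder,
        deriv=params.deriv_order,
        delta=grid.spacing,
        axis=-1,
        mode="interp",
    )
    if not np.all(np.isfinite(out)):
        raise ValueError("S-G derivative produced non-finite values")
    return out


def preprocess_dataset(ds: SpectraDataset, params: SgParams = SgParams()) -> SpectraDataset:
    """Row-wise S-G derivative of a whole dataset; labels and split untouched."""
    deriv = sg_derivative(ds.absorbance, ds.grid, params)
    return SpectraDataset(deriv, ds.labels.copy(), ds.split.copy(), ds.grid, list(ds.class_names))
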