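"""Row-wise spectral pretreatments: SNV, Savitzky-Golay smoothing and D2.

Three classical chemometric pretreatments, each targeting a different
nuisance in diffuse-reflectance NIR spectra:

* **SNV** (standard normal variate) standardises each spectrum to mean 0
  and standard deviation 1, removing additive offsets and multiplicative
  scatter.
* **Smoothing** (Savitzky-Golay, derivative order 0) attenuates
  uncorrelated measurement noise.
* **D2** (Savitzky-Golay second derivative) annihilates constant and
  linear baselines and sharpens overlapping bands.

Exactly one pretreatment is applied per model run; they are alternatives
to be compared, not a chain. Both the plain functions and sklearn-style
transformers (:class:`SNV`, :class:`SavitzkyGolay`) are provided; the
transformers are stateless and exist so pretreatments drop into sklearn
pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator, TransformerMixin

from .dataset import SpectralDataset


class Method(str, Enum):
    """Admitted pretreatment methods."""

    RAW = "raw"
    SNV = "snv"
    D2 = "d2"
    SMOOTH = "smooth"


@dataclass(frozen=True)
class PreprocessConfig:
    """Which pretreatment to run and the Savitzky-Golay filter parameters.

    ``sg_window`` is in grid points (odd, >= 5); ``sg_polyorder`` must be
    below the window and at least 2 for a second derivative. Defaults
    (window 11, polyorder 2 for smoothing / 3 for D2) are common practice
    for ~2 cm^-1-spaced FT-NIR grids.
    """

    method: Method = Method.RAW
    sg_window: int = 11
    sg_polyorder: int | None = None

    def resolved_polyorder(self) -> int:
        if self.sg_polyorder is not None:
            return self.sg_polyorder
        return 3 if self.method is Method.D2 else 2

    def validate(self) -> None:
        method = Method(self.method)
        if method in (Method.D2, Method.SMOOTH):
            order = self.resolved_polyorder()
            if self.sg_window < 5 or self.sg_window % 2 == 0:
                raise ValueError(f"sg_window must be odd and >= 5, got {self.sg_window}")
            if order >= self.sg_window:
                raise ValueError("sg_polyorder must be < sg_window")
            if method is Method.D2 and order < 2:
                raise ValueError("a second derivative needs sg_polyorder >= 2")
            if method is Method.SMOOTH and order < 1:
                raise ValueError("smoothing needs sg_polyorder >= 1")


def snv(X: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-row (x - mean) / sd, sd with ddof=1.

    Any per-spectrum affine distortion a*x + b (a > 0) maps to the same
    output as x, which is exactly why SNV removes multiplicative scatter
    and additive offsets.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("snv expects an n x p matrix with p >= 2")
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    degenerate = np.flatnonzero(sd.ravel() == 0)
    if degenerate.size:
        raise ValueError(
            f"constant spectrum (zero within-spectrum sd) at row index {degenerate[0]}"
        )
    return (X - mean) / sd


def savitzky_golay(
    X: np.ndarray,
    window: int,
    polyorder: int,
    deriv: int = 0,
    spacing: float = 1.0,
) -> np.ndarray:
    """Row-wise Savitzky-Golay filtering on an evenly spaced grid.

    ``deriv=0`` smooths; ``deriv=2`` returns the second derivative with
    respect to the axis variable (scaled by 1/spacing**2). Edges are
    handled by evaluating the local polynomial fitted at the boundary, so
    the output keeps all p columns.
    """
    X = np.asarray(X, dtype=float)
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if X.shape[-1] < window:
        raise ValueError(f"need p >= window, got p={X.shape[-1]} < window={window}")
    return savgol_filter(
        X, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=spacing, axis=-1, mode="interp",
    )


def apply_preprocessing(dataset: SpectralDataset, config: PreprocessConfig) -> SpectralDataset:
    """Dispatch one pretreatment over a dataset; axis and labels unchanged."""
    config.validate()
    method = Method(config.method)
    if method is Method.RAW:
        return dataset
    if method is Method.SNV:
        return dataset.with_absorbance(snv(dataset.absorbance))
    spacing = float(np.mean(np.diff(dataset.wavenumbers)))
    deriv = 2 if method is Method.D2 else 0
    return dataset.with_absorbance(
        savitzky_golay(
            dataset.absorbance, config.sg_window, config.resolved_polyorder(),
            deriv=deriv, spacing=spacing,
        )
    )


class SNV(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer applying the SNV row standardisation."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return snv(X)


class SavitzkyGolay(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer for SG smoothing or differentiation.

    Parameters mirror :func:`savitzky_golay`; ``spacing`` is the grid step
    in cm^-1 so derivative units are absorbance per cm^-1 squared.
    """

    def __init__(self, window: int = 11, polyorder: int = 2, deriv: int = 0,
                 spacing: float = 1.0):
        self.window = window
        self.polyorder = polyorder
        self.deriv = deriv
        self.spacing = spacing

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return savitzky_golay(X, self.window, self.polyorder, self.deriv, self.spacing)
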