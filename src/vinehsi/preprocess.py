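"""Spectral preprocessing grid: SNV + de-trending and Savitzky-Golay derivatives.

Two factors are crossed: scatter correction (standard normal variate
followed by polynomial de-trending, or complete omission) and smoothing
(Savitzky-Golay derivative of order 1 or 2 with window 5, 9 or 15), giving
the 12 preprocessing cells of the factorial experiment.  All transforms are
strictly per-row, so there is no leakage across samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .dataset_builder import SampleTable
from .segmentation import savgol

__all__ = ["PreprocessConfig", "snv", "detrend", "apply_preprocess",
           "enumerate_preprocess_grid"]

DERIV_ORDERS = (1, 2)
SG_WINDOWS = (5, 9, 15)


@dataclass(frozen=True)
class PreprocessConfig:
    """One preprocessing cell: scatter on/off x derivative order x window."""

    scatter: bool
    deriv_order: int
    sg_window: int
    sg_polyorder: int = 2

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError("sg_window must be odd")
        if self.sg_polyorder < self.deriv_order:
            raise ValueError("sg_polyorder must be >= deriv_order")
        if self.sg_window <= self.sg_polyorder:
            raise ValueError("sg_window must be > sg_polyorder")

    def label(self) -> str:
        scatter = "snv+dt" if self.scatter else "none"
        return f"scatter={scatter},deriv={self.deriv_order},window={self.sg_window}"


def snv(spectrum: np.ndarray) -> np.ndarray:
    """Standard normal variate: centre and scale one spectrum to mean 0, sd 1.

    The sample (n-1) standard-deviation convention is used; the two sd
    conventions differ only by a global scalar, to which correlation and
    the downstream classifiers are insensitive.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.ndim != 1 or spectrum.size < 2:
        raise ValueError("snv expects a vector of length >= 2")
    sd = spectrum.std(ddof=1)
    if sd == 0:
        raise ValueError("snv undefined for a zero-variance spectrum")
    return (spectrum - spectrum.mean()) / sd


def detrend(spectrum: np.ndarray, degree: int = 2) -> np.ndarray:
    """Residuals of a least-squares polynomial (default quadratic) in band index.

    Removes the low-order baseline that scatter superimposes on the signal.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.ndim != 1:
        raise ValueError("detrend expects a vector")
    if spectrum.size <= degree + 1:
        raise ValueError(f"need more than {degree + 1} points for a degree-{degree} fit")
    x = np.arange(spectrum.size, dtype=float)
    coeffs = np.polynomial.polynomial.polyfit(x, spectrum, degree)
    return spectrum - np.polynomial.polynomial.polyval(x, coeffs)


def apply_preprocess(table: SampleTable, config: PreprocessConfig) -> SampleTable:
    """Apply one preprocessing cell to every row of a sample table.

    Per row: SNV then de-trend (if ``config.scatter``), then the
    Savitzky-Golay derivative.  Labels and band count are untouched.
    """
    features = table.features
    if config.scatter:
        rows = []
        for i in range(features.shape[0]):
            try:
                rows.append(detrend(snv(features[i])))
            except ValueError as exc:
                raise ValueError(f"sample {table.sample_id[i]!r}: {exc}") from exc
        features = np.stack(rows)
    features = savgol(features, config.sg_window, config.sg_polyorder, config.deriv_order)
    return replace_features(table, features)


def replace_features(table: SampleTable, features: np.ndarray) -> SampleTable:
    return SampleTable(
        features=features,
        variety=table.variety,
        day=table.day,
        sample_id=table.sample_id,
        wavelengths=table.wavelengths,
    )


def enumerate_preprocess_grid() -> list[PreprocessConfig]:
    """All 12 preprocessing cells (2 scatter x 2 derivative orders x 3 windows)."""
    return [
        PreprocessConfig(scatter=s, deriv_order=d, sg_window=w)
        for s, d, w in product((False, True), DERIV_ORDERS, SG_WINDOWS)
    ]
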