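"""Leaf segmentation by spectral-signature correlation.

Each image column (one scanline of n pixels) is processed independently.
Every pixel spectrum and a reference *signature* leaf spectrum are put
through the same Savitzky-Golay smoothing + derivative; a pixel is flagged
as leaf when the Pearson correlation between the two derivative spectra is
strictly greater than a threshold (0.90 by default).  The flagged pixels'
*untransformed* absorbance spectra are then averaged into one mean spectrum
per column — the derivative is used only for the comparison.

The signature is, in the field workflow, a manually selected average leaf
spectrum from the image itself; :func:`extract_signature` averages a
user-specified rectangular region to reproduce that selection without a GUI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .cube import SpectralCube

__all__ = [
    "SegmentationParams",
    "ColumnMeans",
    "SegmentationStats",
    "savgol",
    "pearson_r",
    "segment_column",
    "segment_cube",
    "extract_signature",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentationParams:
    """Savitzky-Golay settings used for the correlation step, plus the r threshold.

    Defaults (window 9, order 2, first derivative) are mid-grid values of
    the preprocessing grid with the conventional polynomial order; the
    threshold applies strictly (r > r_threshold).
    """

    sg_window: int = 9
    sg_polyorder: int = 2
    sg_deriv: int = 1
    r_threshold: float = 0.90

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError(f"sg_window must be odd; got {self.sg_window}")
        if self.sg_polyorder >= self.sg_window:
            raise ValueError("sg_polyorder must be < sg_window")
        if self.sg_deriv > self.sg_polyorder:
            raise ValueError("sg_deriv must be <= sg_polyorder")
        if not (-1.0 < self.r_threshold < 1.0):
            raise ValueError("r_threshold must lie in (-1, 1)")


@dataclass
class ColumnMeans:
    """Per-column mean leaf spectra for the columns that had any leaf pixel.

    ``spectra`` is (m', b) with m' <= m; ``column_index`` records which
    source column produced each row and ``pixels_used`` how many pixels
    went into each mean.
    """

    spectra: np.ndarray
    column_index: np.ndarray
    pixels_used: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.spectra = np.atleast_2d(np.asarray(self.spectra, dtype=float))
        self.column_index = np.asarray(self.column_index, dtype=int)
        self.pixels_used = np.asarray(self.pixels_used, dtype=int)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.spectra.size and np.any(self.pixels_used < 1):
            raise ValueError("every retained column must have pixels_used >= 1")

    @property
    def n_columns(self) -> int:
        return 0 if self.spectra.size == 0 else self.spectra.shape[0]


@dataclass(frozen=True)
class SegmentationStats:
    mean_pixels_per_column: float
    leaf_fraction_observed: float
    columns_empty: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.leaf_fraction_observed <= 1.0):
            raise ValueError("leaf_fraction_observed must lie in [0, 1]")


def savgol(spectrum: np.ndarray, window: int, polyorder: int, deriv: int = 0) -> np.ndarray:
    """Savitzky-Golay smoothing / derivative along the last axis.

    Each output point is the ``deriv``-th derivative at the window centre
    of the local least-squares polynomial fit of the given order, with band
    index as the abscissa (unit spacing).  Ends are handled by fitting the
    edge polynomial and evaluating it over the truncated range
    (scipy ``mode="interp"``).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if window % 2 == 0:
        raise ValueError(f"window must be odd; got {window}")
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if deriv > polyorder:
        raise ValueError("deriv must be <= polyorder")
    if spectrum.shape[-1] < window:
        raise ValueError(f"spectrum length {spectrum.shape[-1]} shorter than window {window}")
    return savgol_filter(spectrum, window, polyorder, deriv=deriv, delta=1.0,
                         axis=-1, mode="interp")


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation between two spectra.

    A zero-variance input cannot be correlated; it is logged and returns
    ``-inf`` so that thresholding treats it as a non-match.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"expected two equal-length vectors; got {a.shape} and {b.shape}")
    if a.size < 3:
        raise ValueError("need at least 3 points to correlate")
    da = a - a.mean()
    db = b - b.mean()
    na = np.sqrt(da @ da)
    nb = np.sqrt(db @ db)
    if na == 0.0 or nb == 0.0:
        logger.debug("pearson_r: zero-variance spectrum treated as non-match")
        return float("-inf")
    return float(np.clip((da @ db) / (na * nb), -1.0, 1.0))


def _correlate_rows(pixels_d: np.ndarray, sig_d: np.ndarray) -> np.ndarray:
    """Pearson r of each row of ``pixels_d`` against ``sig_d``; zero-variance rows -> -inf."""
    dp = pixels_d - pixels_d.mean(axis=-1, keepdims=True)
    ds = sig_d - sig_d.mean()
    ns = np.sqrt(ds @ ds)
    np_rows = np.sqrt(np.einsum("...b,...b->...", dp, dp))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.einsum("...b,b->...", dp, ds) / (np_rows * ns)
    r = np.where((np_rows == 0) | (ns == 0), -np.inf, r)
    return np.clip(r, -1.0, 1.0, out=np.asarray(r, dtype=float))


def segment_column(column: np.ndarray, signature: np.ndarray,
                   params: SegmentationParams = SegmentationParams(),
                   ) -> tuple[np.ndarray, np.ndarray | None]:
    """Flag the leaf pixels of one (n, b) column and average them.

    Returns ``(leaf_flags, column_mean)`` where ``column_mean`` is the plain
    average of the flagged pixels' untransformed absorbance spectra, or
    ``None`` when no pixel passes the threshold.
    """
    column = np.atleast_2d(np.asarray(column, dtype=float))
    signature = np.asarray(signature, dtype=float)
    if column.shape[1] != signature.shape[0]:
        raise ValueError(
            f"band mismatch: column has {column.shape[1]} bands, signature {signature.shape[0]}"
        )
    sig_d = savgol(signature, params.sg_window, params.sg_polyorder, params.sg_deriv)
    pix_d = savgol(column, params.sg_window, params.sg_polyorder, params.sg_deriv)
    r = _correlate_rows(pix_d, sig_d)
    flags = r > params.r_threshold
    if not flags.any():
        return flags, None
    return flags, column[flags].mean(axis=0)


def segment_cube(cube: SpectralCube, signature: np.ndarray,
                 params: SegmentationParams = SegmentationParams(),
                 ) -> tuple[ColumnMeans, SegmentationStats, np.ndarray]:
    """Segment every column of an absorbance cube against the signature.

    Columns with no matching pixel are excluded from :class:`ColumnMeans`
    but counted in the stats.  Returns ``(means, stats, mask)`` with
    ``mask`` the (m, n) boolean leaf map.
    """
    if cube.unit != "absorbance":
        raise ValueError(f"segment_cube expects an absorbance cube; got unit {cube.unit!r}")
    signature = np.asarray(signature, dtype=float)
    if signature.shape != (cube.n_bands,):
        raise ValueError(
            f"signature has {signature.shape[0]} bands but cube has {cube.n_bands}"
        )
    sig_d = savgol(signature, params.sg_window, params.sg_polyorder, params.sg_deriv)
    pix_d = savgol(cube.values, params.sg_window, params.sg_polyorder, params.sg_deriv)
    mask = _correlate_rows(pix_d, sig_d) > params.r_threshold  # (m, n)

    counts = mask.sum(axis=1)
    retained = np.nonzero(counts > 0)[0]
    spectra = np.empty((len(retained), cube.n_bands))
    for i, j in enumerate(retained):
        spectra[i] = cube.values[j][mask[j]].mean(axis=0)
    means = ColumnMeans(
        spectra=spectra if len(retained) else np.empty((0, cube.n_bands)),
        column_index=retained,
        pixels_used=counts[retained],
        wavelengths=cube.wavelengths,
    )
    stats = SegmentationStats(
        mean_pixels_per_column=float(counts.mean()) if counts.size else 0.0,
        leaf_fraction_observed=float(mask.mean()) if mask.size else 0.0,
        columns_empty=int(cube.n_columns - len(retained)),
    )
    return means, stats, mask


def extract_signature(cube: SpectralCube, columns: slice, rows: slice) -> np.ndarray:
    """Average a rectangular region of the cube into a signature spectrum."""
    region = cube.values[columns, rows, :]
    if region.size == 0:
        raise ValueError("signature region is empty")
    return region.reshape(-1, cube.n_bands).mean(axis=0)
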