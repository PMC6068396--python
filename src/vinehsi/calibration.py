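"""Radiometric calibration: raw counts -> reflectance -> absorbance, band trimming.

Under natural illumination the camera records light intensity G.  A white
reference W (near-perfect diffuse reflector imaged statically at the start
of each recording) and a dark-current frame D (lens covered) turn counts
into reflectance per row-pixel and band::

    R = (G - D) / (W - D)

Absorbance is the chemometric log-transform A = log10(1/R).  The first and
last bands of the spectral range carry most of the sensor noise and are
discarded (25 each side by default, 300 -> 250 bands).
"""

from __future__ import annotations

import logging

import numpy as np

from .cube import ReferenceFrames, SpectralCube

__all__ = ["CalibrationError", "to_reflectance", "to_absorbance", "trim_bands"]

logger = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """Raised when the white/dark frames cannot calibrate the cube."""


def to_reflectance(cube: SpectralCube, refs: ReferenceFrames) -> SpectralCube:
    """Convert a raw-intensity cube to reflectance, R = (G - D) / (W - D).

    The white and dark frames live on the (row-pixel x band) grid and are
    broadcast across columns.  Reflectance above 1 is permitted (targets
    brighter than the panel under illumination drift); only a non-positive
    denominator is an error.
    """
    if cube.unit != "raw":
        raise ValueError(f"to_reflectance expects a raw cube; got unit {cube.unit!r}")
    if refs.shape != (cube.n_rows, cube.n_bands):
        raise ValueError(
            f"reference frames {refs.shape} do not match cube grid "
            f"{(cube.n_rows, cube.n_bands)}"
        )
    denom = refs.white - refs.dark
    bad = denom <= 0
    if np.any(bad):
        rows, bands = np.nonzero(bad)
        cells = ", ".join(f"(row={r}, band={b})" for r, b in zip(rows[:10], bands[:10]))
        more = "" if len(rows) <= 10 else f" and {len(rows) - 10} more"
        raise CalibrationError(f"white - dark <= 0 at {cells}{more}")
    values = (cube.values - refs.dark) / denom
    return SpectralCube(values, cube.wavelengths, unit="reflectance")


def to_absorbance(cube: SpectralCube, floor: float = 1e-6) -> SpectralCube:
    """Convert reflectance to absorbance, A = log10(1 / max(R, floor)).

    ``floor`` guards against non-positive reflectance on dark pixels; its
    default (1e-6) is far below the leaf reflectance range so leaf spectra
    are unaffected.  Floored cells are counted and logged, never fatal.
    """
    if cube.unit != "reflectance":
        raise ValueError(f"to_absorbance expects a reflectance cube; got unit {cube.unit!r}")
    if floor <= 0:
        raise ValueError("floor must be positive")
    n_floored = int(np.count_nonzero(cube.values < floor))
    if n_floored:
        logger.info("to_absorbance: floored %d cells with R < %g", n_floored, floor)
    values = -np.log10(np.maximum(cube.values, floor))
    return SpectralCube(values, cube.wavelengths, unit="absorbance")


def trim_bands(data, n_discard: int = 25):
    """Discard the first and last ``n_discard`` noisy bands.

    Accepts a :class:`SpectralCube` (wavelength axis sliced consistently)
    or a bare array whose *last* axis is the band axis.  Interior bands are
    kept exactly — this is a slice, not a resampling.
    """
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    if isinstance(data, SpectralCube):
        b = data.n_bands
        if b <= 2 * n_discard:
            raise ValueError(f"cannot discard 2 x {n_discard} bands from a {b}-band cube")
        sl = slice(n_discard, b - n_discard)
        return SpectralCube(data.values[:, :, sl], data.wavelengths[sl], unit=data.unit)
    arr = np.asarray(data)
    b = arr.shape[-1]
    if b <= 2 * n_discard:
        raise ValueError(f"cannot discard 2 x {n_discard} bands from a {b}-band axis")
    return arr[..., n_discard : b - n_discard]
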