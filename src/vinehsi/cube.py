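"""Hyperspectral cube containers and ENVI header + BIL binary I/O.

A push-broom camera acquires one scanline (here called a *column*) at a
time: a 1-D spatial line of ``n`` pixels, each carrying a full spectrum of
``b`` bands.  Platform motion accumulates ``m`` such columns into a cube.
The in-memory layout is ``values[m, n, b]`` (columns x row-pixels x bands).

On disk, cubes are stored in the de-facto hyperspectral exchange format: a
plain-text ENVI header (``.hdr``) next to a raw band-interleaved-by-line
(BIL) binary (``.img``).  One ENVI *line* maps to one column of the cube,
ENVI *samples* to the row-pixels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SpectralCube",
    "ReferenceFrames",
    "EnviFormatError",
    "write_envi_array",
    "read_envi_array",
    "reduce_static_frames",
]

#: allowed unit tags and the only legal transitions between them
UNITS = ("raw", "reflectance", "absorbance")

# ENVI data-type codes we support (code -> numpy dtype)
_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 4: np.float32, 5: np.float64, 12: np.uint16}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


class EnviFormatError(ValueError):
    """Raised when an ENVI header/binary pair is internally inconsistent."""


@dataclass
class SpectralCube:
    """A hyperspectral image: ``values[m, n, b]`` plus its wavelength axis.

    Parameters
    ----------
    values
        3-D array, axes = (columns m, row-pixels n, bands b).
    wavelengths
        Strictly increasing band centres in nm, length ``b``.
    unit
        One of ``"raw"`` (camera counts), ``"reflectance"`` or
        ``"absorbance"`` (log10 1/R).
    """

    values: np.ndarray
    wavelengths: np.ndarray
    unit: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"cube values must be 3-D (m, n, b); got shape {self.values.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.values.shape[2]:
            raise ValueError(
                f"wavelength axis length {len(self.wavelengths)} does not match "
                f"band count {self.values.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.unit not in UNITS:
            raise ValueError(f"unit must be one of {UNITS}; got {self.unit!r}")

    @property
    def n_columns(self) -> int:
        return self.values.shape[0]

    @property
    def n_rows(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class ReferenceFrames:
    """White-reference and dark-current frames on the (row-pixel x band) grid.

    ``white`` is the intensity of light from a diffusely reflecting panel
    (e.g. Spectralon) imaged statically; ``dark`` is the sensor's inherent
    electronic noise measured with the lens covered.  Both are ``(n, b)``.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=float)
        self.dark = np.asarray(self.dark, dtype=float)
        if self.white.ndim != 2 or self.white.shape != self.dark.shape:
            raise ValueError(
                f"white {self.white.shape} and dark {self.dark.shape} must be "
                "matching 2-D (rows, bands) arrays"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.white.shape


def reduce_static_frames(stack: np.ndarray) -> np.ndarray:
    """Average a static multi-column recording ``(cols, n, b)`` to one ``(n, b)`` frame.

    Reference panels are imaged statically for some number of scanlines;
    the columns are averaged into a single frame before calibration.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        return stack
    if stack.ndim != 3:
        raise ValueError(f"expected (cols, rows, bands) stack; got shape {stack.shape}")
    return stack.mean(axis=0)


# ---------------------------------------------------------------------------
# ENVI header + BIL binary


def _format_header(shape: tuple[int, int, int], dtype: np.dtype,
                   wavelengths: np.ndarray | None, extra: dict[str, str]) -> str:
    m, n, b = shape
    lines = [
        "ENVI",
        f"samples = {n}",
        f"lines = {m}",
        f"bands = {b}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[np.dtype(dtype)]}",
        "interleave = bil",
        "byte order = 0",
    ]
    for key, val in extra.items():
        lines.append(f"{key} = {val}")
    if wavelengths is not None:
        wl = ", ".join(repr(float(w)) for w in wavelengths)
        lines.append("wavelength units = Nanometers")
        lines.append("wavelength = {%s}" % wl)
    return "\n".join(lines) + "\n"


def _parse_header(text: str) -> dict[str, str]:
    if not text.lstrip().startswith("ENVI"):
        raise EnviFormatError("not an ENVI header: missing 'ENVI' magic line")
    # join brace-delimited multi-line values, then split on key = value
    text = text.lstrip()[4:]
    fields: dict[str, str] = {}
    pattern = re.compile(r"^\s*([\w ]+?)\s*=\s*(\{[^}]*\}|[^\n]*)", re.MULTILINE | re.DOTALL)
    for match in pattern.finditer(text):
        key = match.group(1).strip().lower()
        fields[key] = match.group(2).strip()
    return fields


def write_envi_array(stem: str | Path, values: np.ndarray,
                     wavelengths: np.ndarray | None = None,
                     extra: dict[str, str] | None = None) -> tuple[Path, Path]:
    """Write a ``(m, n, b)`` array as ``<stem>.hdr`` + ``<stem>.img`` (BIL).

    Returns the (header, binary) paths.  2-D inputs ``(n, b)`` — reference
    frames — are written as single-line images.
    """
    values = np.asarray(values)
    if values.ndim == 2:
        values = values[None, :, :]
    if values.ndim != 3:
        raise ValueError(f"expected 2-D or 3-D array; got shape {values.shape}")
    if np.dtype(values.dtype) not in _DTYPE_CODES:
        values = values.astype(np.float64)
    stem = Path(stem)
    hdr_path = stem.with_suffix(".hdr")
    img_path = stem.with_suffix(".img")
    hdr_path.write_text(_format_header(values.shape, values.dtype, wavelengths, extra or {}))
    # BIL: per line, bands x samples
    bil = np.ascontiguousarray(values.transpose(0, 2, 1))
    bil.tofile(img_path)
    return hdr_path, img_path


def read_envi_array(stem: str | Path) -> tuple[np.ndarray, np.ndarray | None, dict[str, str]]:
    """Read ``<stem>.hdr`` + ``<stem>.img`` back into ``(values, wavelengths, fields)``.

    Raises :class:`EnviFormatError` naming the offending field when the
    header is inconsistent with the binary (size mismatch, wavelength list
    length != bands, unsupported interleave/dtype).
    """
    stem = Path(stem)
    hdr_path = stem.with_suffix(".hdr")
    img_path = stem.with_suffix(".img")
    fields = _parse_header(hdr_path.read_text())

    def _int(key: str) -> int:
        if key not in fields:
            raise EnviFormatError(f"header missing required field {key!r}")
        try:
            return int(fields[key])
        except ValueError as exc:
            raise EnviFormatError(f"header field {key!r} is not an integer: {fields[key]!r}") from exc

    m, n, b = _int("lines"), _int("samples"), _int("bands")
    dtype_code = _int("data type")
    if dtype_code not in _ENVI_DTYPES:
        raise EnviFormatError(f"unsupported 'data type' code {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    interleave = fields.get("interleave", "bil").lower()
    if interleave != "bil":
        raise EnviFormatError(f"unsupported 'interleave' {interleave!r}; only bil is handled")
    if int(fields.get("byte order", "0")) != 0:
        raise EnviFormatError("unsupported 'byte order'; only little-endian (0) is handled")

    expected_bytes = m * n * b * dtype.itemsize
    actual_bytes = img_path.stat().st_size
    if expected_bytes != actual_bytes:
        raise EnviFormatError(
            f"binary size mismatch: 'lines'/'samples'/'bands'/'data type' imply "
            f"{expected_bytes} bytes but {img_path.name} holds {actual_bytes}"
        )
    raw = np.fromfile(img_path, dtype=dtype).reshape(m, b, n)
    values = np.ascontiguousarray(raw.transpose(0, 2, 1))

    wavelengths = None
    if "wavelength" in fields:
        body = fields["wavelength"].strip()
        if not (body.startswith("{") and body.endswith("}")):
            raise EnviFormatError("header field 'wavelength' is not a {...} list")
        wavelengths = np.array([float(x) for x in body[1:-1].split(",") if x.strip()])
        if len(wavelengths) != b:
            raise EnviFormatError(
                f"header field 'wavelength' lists {len(wavelengths)} values "
                f"but 'bands' = {b}"
            )
    return values, wavelengths, fields
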