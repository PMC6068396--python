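"""Reduce per-column mean spectra to a fixed number of samples per variety-day.

For each variety-day image the retained column means are divided into 40
consecutive sets of ~m/40 spectra each; averaging each set yields 40
labeled samples per variety-day.  With 30 varieties and 2 measurement
days this gives the 2,400-sample dataset (80 per variety) used for
classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .segmentation import ColumnMeans

__all__ = [
    "SampleTable",
    "TableFormatError",
    "partition_consecutive",
    "build_samples",
    "assemble",
    "write_table",
    "read_table",
]


class TableFormatError(ValueError):
    """Raised when a sample-table CSV is malformed."""


@dataclass
class SampleTable:
    """Labeled matrix of averaged leaf spectra.

    rows = samples, columns = spectral bands; each row carries a variety
    label, a measurement-day label and a unique sample id.
    """

    features: np.ndarray
    variety: np.ndarray
    day: np.ndarray
    sample_id: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.variety = np.asarray(self.variety)
        self.day = np.asarray(self.day)
        self.sample_id = np.asarray(self.sample_id)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        n, b = self.features.shape
        for name, arr in (("variety", self.variety), ("day", self.day),
                          ("sample_id", self.sample_id)):
            if arr.shape != (n,):
                raise ValueError(f"{name} has shape {arr.shape}; expected ({n},)")
        if self.wavelengths.shape != (b,):
            raise ValueError(f"wavelengths has length {len(self.wavelengths)}; expected {b}")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        if len(np.unique(self.sample_id)) != n:
            raise TableFormatError("sample_id values are not unique")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_bands(self) -> int:
        return self.features.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.variety)

    def class_counts(self) -> dict:
        labels, counts = np.unique(self.variety, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "sample_id": self.sample_id,
            "variety": self.variety,
            "day": self.day,
        })
        bands = pd.DataFrame(self.features, columns=[f"{w:g}" for w in self.wavelengths])
        return pd.concat([df, bands], axis=1)


def partition_consecutive(m: int, n_sets: int = 40) -> list[range]:
    """Split ``range(m)`` into ``n_sets`` consecutive, exhaustive index ranges.

    Sizes differ by at most 1; when m is not divisible the remainder goes
    to the earliest sets (deterministic, order-preserving).
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if m < n_sets:
        raise ValueError(f"cannot split {m} columns into {n_sets} sets")
    base, rem = divmod(m, n_sets)
    ranges: list[range] = []
    start = 0
    for i in range(n_sets):
        size = base + (1 if i < rem else 0)
        ranges.append(range(start, start + size))
        start += size
    return ranges


def build_samples(columns: ColumnMeans, n_sets: int, variety, day) -> SampleTable:
    """Average consecutive sets of column means into labeled samples.

    One row per set, each the arithmetic mean of its range's column
    spectra, labeled ``(variety, day)``.  Only retained (non-empty)
    columns participate.
    """
    m = columns.n_columns
    if m < n_sets:
        raise ValueError(
            f"variety-day ({variety}, {day}): only {m} retained columns for {n_sets} sets"
        )
    ranges = partition_consecutive(m, n_sets)
    features = np.stack([columns.spectra[r.start : r.stop].mean(axis=0) for r in ranges])
    ids = np.array([f"{variety}-d{day}-s{i:03d}" for i in range(n_sets)])
    return SampleTable(
        features=features,
        variety=np.full(n_sets, variety),
        day=np.full(n_sets, day),
        sample_id=ids,
        wavelengths=columns.wavelengths,
    )


def assemble(parts: Iterable[SampleTable]) -> SampleTable:
    """Concatenate per-variety-day tables into one dataset.

    All parts must share the same wavelength axis; the result's row count
    is the sum of its parts (30 varieties x 2 days x 40 sets -> 2,400).
    """
    parts = list(parts)
    if not parts:
        raise ValueError("nothing to assemble")
    wl = parts[0].wavelengths
    for p in parts[1:]:
        if p.wavelengths.shape != wl.shape or not np.allclose(p.wavelengths, wl):
            raise ValueError("wavelength axes differ between parts")
    return SampleTable(
        features=np.vstack([p.features for p in parts]),
        variety=np.concatenate([p.variety for p in parts]),
        day=np.concatenate([p.day for p in parts]),
        sample_id=np.concatenate([p.sample_id for p in parts]),
        wavelengths=wl,
    )


def write_table(table: SampleTable, path: str | Path) -> Path:
    """Write a sample table as CSV at full float precision."""
    path = Path(path)
    table.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def read_table(path: str | Path) -> SampleTable:
    """Read a sample-table CSV written by :func:`write_table`."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TableFormatError(f"malformed sample-table CSV {path}: {exc}") from exc
    for col in ("sample_id", "variety", "day"):
        if col not in df.columns:
            raise TableFormatError(f"sample-table CSV missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise TableFormatError(f"duplicated sample_id values: {dupes[:5]}")
    band_cols = [c for c in df.columns if c not in ("sample_id", "variety", "day")]
    if not band_cols:
        raise TableFormatError("sample-table CSV has no band columns")
    try:
        wavelengths = np.array([float(c) for c in band_cols])
    except ValueError as exc:
        raise TableFormatError(f"band column names must be wavelengths: {exc}") from exc
    features = df[band_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(features)):
        raise TableFormatError("sample-table CSV contains missing/non-finite values")
    return SampleTable(
        features=features,
        variety=df["variety"].to_numpy(),
        day=df["day"].to_numpy(),
        sample_id=df["sample_id"].astype(str).to_numpy(),
        wavelengths=wavelengths,
    )
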