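"""Synthetic hyperspectral scenes emulating on-the-go vineyard acquisition.

The field study this pipeline targets is not deposited, so every stage is
exercised on generated data: smooth leaf-like variety signatures, push-broom
cubes with ground-truth leaf masks and calibration frames, and (as a fast
path that bypasses the imaging stage) ready-made labeled sample tables.

Emulation targets: 300 bands over 400-1,000 nm, 900-pixel scanlines,
~1,800 columns per variety-day image, ~53.4% leaf pixels per column,
30 variety classes x 2 measurement days, per-column multiplicative
illumination variation and additive sensor noise.  The generator makes no
claim of radiative-transfer realism; class separability is a single knob
(``separation``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cube import ReferenceFrames, SpectralCube, read_envi_array, write_envi_array
from .dataset_builder import SampleTable

__all__ = [
    "VarietySignature",
    "SceneConfig",
    "RawScene",
    "StudyDesign",
    "STUDY",
    "make_signatures",
    "make_background_signatures",
    "render_scene",
    "make_sample_table",
    "write_envi",
    "read_envi",
]

#: spectral range of the emulated VNIR camera, nm
WAVELENGTH_RANGE = (400.0, 1000.0)

# shared absorption features of the base leaf curve: (centre nm, width nm, amplitude)
# chlorophyll bands in the visible, a water band near 970 nm, low NIR baseline
_BASE_FEATURES = (
    (430.0, 30.0, 0.50),
    (490.0, 28.0, 0.30),
    (620.0, 30.0, 0.25),
    (665.0, 22.0, 0.45),
    (970.0, 28.0, 0.15),
)
_BASE_OFFSET = 0.25


@dataclass(frozen=True)
class VarietySignature:
    """One variety's reference leaf spectrum in absorbance units."""

    variety_id: str
    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", np.asarray(self.wavelengths, dtype=float))
        object.__setattr__(self, "absorbance", np.asarray(self.absorbance, dtype=float))
        if self.wavelengths.shape != self.absorbance.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and absorbance must be matching vectors")
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)) or np.any(self.absorbance < 0):
            raise ValueError("absorbance must be finite and non-negative")

    @property
    def n_bands(self) -> int:
        return len(self.wavelengths)


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and noise settings of one rendered variety-day image.

    ``illumination_drift`` is the (low, high) range of the per-column
    multiplicative illumination factor; ``noise_sd`` is additive sensor
    noise in raw counts (the synthetic white peaks near 3,500 counts).
    """

    n_columns: int
    n_rows: int = 900
    n_bands: int = 300
    leaf_fraction: float = 0.534
    illumination_drift: tuple[float, float] = (0.95, 1.05)
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_columns < 40:
            raise ValueError("n_columns must be >= 40 (one sample set per image slice)")
        if self.n_rows < 1 or self.n_bands < 5:
            raise ValueError("n_rows must be >= 1 and n_bands >= 5")
        if not (0.0 <= self.leaf_fraction <= 1.0):
            raise ValueError("leaf_fraction must lie in [0, 1]")
        lo, hi = self.illumination_drift
        if not (0 < lo <= hi):
            raise ValueError("illumination_drift must be (low, high) with 0 < low <= high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def n_pixels(self) -> int:
        """Spectra per image = columns x row-pixels."""
        return self.n_columns * self.n_rows


@dataclass(frozen=True)
class StudyDesign:
    """The emulated study layout; products of these counts drive the pipeline."""

    n_varieties: int = 30
    n_days: int = 2
    columns_per_image: int = 1800
    rows_per_column: int = 900
    n_bands: int = 300
    n_discard: int = 25
    sets_per_image: int = 40

    @property
    def n_images(self) -> int:
        return self.n_varieties * self.n_days

    @property
    def pixels_per_image(self) -> int:
        return self.columns_per_image * self.rows_per_column

    @property
    def n_samples(self) -> int:
        return self.n_varieties * self.n_days * self.sets_per_image

    @property
    def retained_bands(self) -> int:
        return self.n_bands - 2 * self.n_discard


STUDY = StudyDesign()


@dataclass
class RawScene:
    """A rendered raw-intensity cube with its calibration frames and ground truth."""

    cube: SpectralCube
    white: np.ndarray
    dark: np.ndarray
    truth_mask: np.ndarray
    truth_variety: str

    def __post_init__(self) -> None:
        m, n, b = self.cube.shape
        if self.white.shape != (n, b) or self.dark.shape != (n, b):
            raise ValueError("white/dark frames must match the cube's (rows, bands) grid")
        self.truth_mask = np.asarray(self.truth_mask, dtype=bool)
        if self.truth_mask.shape != (m, n):
            raise ValueError("truth_mask must match the cube's (columns, rows) grid")

    @property
    def refs(self) -> ReferenceFrames:
        return ReferenceFrames(white=self.white, dark=self.dark)


def _wavelength_axis(n_bands: int) -> np.ndarray:
    return np.linspace(*WAVELENGTH_RANGE, n_bands)


def _gauss(wl: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - centre) / width) ** 2)


def _base_curve(wl: np.ndarray) -> np.ndarray:
    curve = np.full_like(wl, _BASE_OFFSET)
    for centre, width, amp in _BASE_FEATURES:
        curve += amp * _gauss(wl, centre, width)
    return curve


def make_signatures(n_varieties: int, n_bands: int, separation: float = 0.5,
                    seed: int = 0) -> list[VarietySignature]:
    """Generate smooth leaf-like variety signatures.

    Each signature is the shared base curve (chlorophyll/water Gaussian
    absorption features) plus variety-specific Gaussian-bump perturbations
    whose magnitude scales linearly with ``separation``; ``separation=0``
    makes all varieties identical.  Deterministic for a fixed seed.
    """
    if n_varieties < 1:
        raise ValueError("n_varieties must be >= 1")
    if n_bands < 5:
        raise ValueError("n_bands must be >= 5")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    wl = _wavelength_axis(n_bands)
    base = _base_curve(wl)
    rng = np.random.default_rng(seed)
    signatures = []
    for v in range(n_varieties):
        bump = np.zeros_like(wl)
        for _ in range(4):
            centre = rng.uniform(420.0, 980.0)
            width = rng.uniform(20.0, 60.0)
            amp = rng.normal(0.0, 0.15)
            bump += amp * _gauss(wl, centre, width)
        absorbance = np.clip(base + separation * bump, 1e-3, None)
        signatures.append(VarietySignature(f"V{v:02d}", wl, absorbance))
    return signatures


def make_background_signatures(n_bands: int, seed: int = 0) -> list[VarietySignature]:
    """Non-leaf scene materials: soil, wood (trellis posts) and sky gaps.

    These are spectrally smooth but lack the leaf absorption features, so
    their derivative spectra decorrelate from any leaf signature.
    """
    wl = _wavelength_axis(n_bands)
    rng = np.random.default_rng(seed)
    x = (wl - wl[0]) / (wl[-1] - wl[0])
    soil = 0.9 - 0.55 * x + 0.05 * np.sin(2 * np.pi * x * (1.5 + 0.2 * rng.random()))
    wood = 1.1 - 0.8 * x + 0.08 * _gauss(wl, 550.0, 80.0)
    sky = np.full_like(wl, 0.05) + 0.15 * x
    out = []
    for name, curve in (("bg:soil", soil), ("bg:wood", wood), ("bg:sky", sky)):
        out.append(VarietySignature(name, wl, np.clip(curve, 1e-3, None)))
    return out


def _make_frames(n_rows: int, n_bands: int, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray]:
    """White panel frame (smooth per-band illumination, mild row variation) and dark frame."""
    wl = _wavelength_axis(n_bands)
    illum = 3500.0 * _gauss(wl, 720.0, 350.0) + 400.0  # solar-ish envelope in counts
    rows = np.linspace(-1.0, 1.0, n_rows)
    row_gain = 1.0 + 0.02 * rng.uniform(-1, 1) * rows + 0.01 * rng.uniform(-1, 1) * rows**2
    white = row_gain[:, None] * illum[None, :]
    dark = 100.0 + rng.normal(0.0, 1.0, size=(n_rows, n_bands))
    return white, dark


def render_scene(config: SceneConfig, signature: VarietySignature,
                 background_signatures: list[VarietySignature] | None = None) -> RawScene:
    """Render one variety-day image as raw camera counts.

    Each column receives Bernoulli(``leaf_fraction``) leaf pixels (recorded
    in ``truth_mask``); leaf pixels carry the variety signature and the rest
    carry background material spectra.  The absorbance scene is inverted to
    raw intensity against the generated white/dark frames
    (G = D + f_col * 10**(-A) * (W - D), with f_col the per-column
    illumination factor), then additive Gaussian sensor noise is applied.
    Deterministic for a fixed ``config.seed``.
    """
    if signature.n_bands != config.n_bands:
        raise ValueError(
            f"signature has {signature.n_bands} bands but config expects {config.n_bands}"
        )
    if background_signatures is None:
        background_signatures = make_background_signatures(config.n_bands, seed=config.seed)
    for bg in background_signatures:
        if bg.n_bands != config.n_bands:
            raise ValueError(f"background {bg.variety_id!r} band count mismatch")

    m, n, b = config.n_columns, config.n_rows, config.n_bands
    rng = np.random.default_rng(config.seed)
    white, dark = _make_frames(n, b, rng)
    truth_mask = rng.random((m, n)) < config.leaf_fraction

    bg_stack = np.stack([bg.absorbance for bg in background_signatures])
    bg_choice = rng.integers(0, len(background_signatures), size=(m, n))
    absorbance = bg_stack[bg_choice]  # (m, n, b)
    absorbance[truth_mask] = signature.absorbance

    lo, hi = config.illumination_drift
    illum = rng.uniform(lo, hi, size=m)
    reflectance = 10.0 ** (-absorbance)
    counts = dark[None, :, :] + illum[:, None, None] * reflectance * (white - dark)[None, :, :]
    if config.noise_sd > 0:
        counts += rng.normal(0.0, config.noise_sd, size=(m, n, b))
    cube = SpectralCube(counts, signature.wavelengths, unit="raw")
    return RawScene(cube=cube, white=white, dark=dark, truth_mask=truth_mask,
                    truth_variety=signature.variety_id)


def make_sample_table(n_varieties: int = 30, n_days: int = 2,
                      samples_per_variety_day: int = 40, n_bands: int = 250,
                      separation: float = 0.5, noise_sd: float = 0.01,
                      seed: int = 0, day_effect: float = 0.01) -> SampleTable:
    """Directly generate a balanced labeled sample table (imaging stage bypassed).

    Rows are variety signatures plus a small global additive day shift
    (``day_effect`` per day index, smaller than the default class
    separation — classes must stay separable across the pooled days) plus
    within-class variation of scale ``noise_sd``.  Because each emulated
    sample is the average of many thousands of pixel spectra, white noise
    is almost entirely averaged away; the variation that survives is
    spectrally *smooth*.  It is modelled per sample as random Gaussian
    bumps of amplitude scale ``noise_sd`` plus a white averaging residual
    of sd ``noise_sd / 50``.  Exactly ``samples_per_variety_day`` rows per
    (variety, day); deterministic for a fixed seed.
    """
    for name, v in (("n_varieties", n_varieties), ("n_days", n_days),
                    ("samples_per_variety_day", samples_per_variety_day),
                    ("n_bands", n_bands)):
        if v < 1:
            raise ValueError(f"{name} must be >= 1")
    signatures = make_signatures(n_varieties, n_bands, separation, seed)
    wl = signatures[0].wavelengths
    rng = np.random.default_rng(seed)
    feats, variety, day, ids = [], [], [], []
    for sig in signatures:
        for d in range(n_days):
            block = sig.absorbance[None, :] + day_effect * d
            if noise_sd > 0:
                deviation = np.zeros((samples_per_variety_day, n_bands))
                for _ in range(3):  # smooth biological/illumination variation
                    centre = rng.uniform(420.0, 980.0, size=samples_per_variety_day)
                    width = rng.uniform(20.0, 60.0, size=samples_per_variety_day)
                    amp = rng.normal(0.0, noise_sd, size=samples_per_variety_day)
                    deviation += amp[:, None] * _gauss(wl[None, :], centre[:, None],
                                                       width[:, None])
                block = block + deviation + rng.normal(
                    0.0, noise_sd / 50.0, size=(samples_per_variety_day, n_bands))
            else:
                block = np.repeat(block, samples_per_variety_day, axis=0)
            feats.append(block)
            variety.extend([sig.variety_id] * samples_per_variety_day)
            day.extend([d] * samples_per_variety_day)
            ids.extend(f"{sig.variety_id}-d{d}-s{i:03d}"
                       for i in range(samples_per_variety_day))
    return SampleTable(
        features=np.vstack(feats),
        variety=np.array(variety),
        day=np.array(day),
        sample_id=np.array(ids),
        wavelengths=signatures[0].wavelengths,
    )


# ---------------------------------------------------------------------------
# Scene persistence (ENVI directory layout)


def write_envi(scene: RawScene, path: str | Path) -> Path:
    """Write a scene to ``path/`` as ENVI pairs (cube, white, dark, mask) + meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    wl = scene.cube.wavelengths
    write_envi_array(path / "cube", scene.cube.values, wl, extra={"spectra units": scene.cube.unit})
    write_envi_array(path / "white", scene.white, wl)
    write_envi_array(path / "dark", scene.dark, wl)
    write_envi_array(path / "mask", scene.truth_mask.astype(np.uint8)[:, :, None])
    (path / "meta.json").write_text(json.dumps({"truth_variety": scene.truth_variety}))
    return path


def read_envi(path: str | Path) -> RawScene:
    """Read back a scene written by :func:`write_envi` (bit-for-bit round trip)."""
    path = Path(path)
    values, wl, fields = read_envi_array(path / "cube")
    unit = fields.get("spectra units", "raw")
    cube = SpectralCube(values, wl, unit=unit)
    white, _, _ = read_envi_array(path / "white")
    dark, _, _ = read_envi_array(path / "dark")
    mask, _, _ = read_envi_array(path / "mask")
    meta = json.loads((path / "meta.json").read_text())
    return RawScene(cube=cube, white=white[0], dark=dark[0],
                    truth_mask=mask[:, :, 0].astype(bool),
                    truth_variety=meta["truth_variety"])
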