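"""Synthetic NIR hypercubes and spectra tables for the variety-discrimination study.

Real Fritillaria bulb spectra are not publicly distributable, so every
downstream stage is exercised on synthetic data that reproduces the
qualitative structure of dried-bulb NIR reflectance on the 874-1734 nm
axis: a gentle rising baseline, shared absorption geometry with reflectance
peaks near 1100 and 1300 nm (flanks of the second C-H stretch overtone) and
valleys near 1200 nm (C-H) and 1460 nm (first O-H overtone, water), small
per-variety amplitude perturbations that overlap heavily between classes,
i.i.d. per-pixel sensor noise, and elevated noise in the unstable leading
and trailing bands of the line-scan camera.

Twelve classes of thirty samples each (n = 360) is the default census.
All randomness flows from the explicit seed in the config; no global RNG
state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cube_io import SpectralCube, ReferencePair
from .tables import SpectraTable

__all__ = [
    "SyntheticConfig",
    "GaussianFeature",
    "make_class_profiles",
    "simulate_spectra_table",
    "simulate_cube",
    "well_separated_config",
]

# (center nm, width nm, signed amplitude) Gaussian bumps shared by all classes
DEFAULT_SHARED_FEATURES: tuple[tuple[float, float, float], ...] = (
    (1100.0, 60.0, +0.12),
    (1300.0, 70.0, +0.10),
    (1200.0, 40.0, -0.08),
    (1460.0, 50.0, -0.15),
)

#: bands outside this window get extra noise (unstable sensor edges)
CLEAN_WINDOW_NM: tuple[float, float] = (975.0, 1646.0)

GaussianFeature = tuple[float, float, float]


def _default_class_deltas(n_classes: int) -> list[list[GaussianFeature]]:
    """Small per-class perturbations: one bump each, centers spread over the
    informative mid-range, alternating sign, amplitude ~0.035 so that class
    mean curves overlap strongly."""
    centers = np.linspace(980.0, 1500.0, n_classes)
    return [
        [(float(c), 45.0, 0.035 * (1 if k % 2 == 0 else -1))]
        for k, c in enumerate(centers)
    ]


@dataclass
class SyntheticConfig:
    """Full recipe for generating synthetic cubes and spectra tables."""

    n_classes: int = 12
    samples_per_class: int = 30
    wavelength_start: float = 874.0
    wavelength_end: float = 1734.0
    n_bands: int = 256
    shared_features: Sequence[GaussianFeature] = DEFAULT_SHARED_FEATURES
    class_deltas: Sequence[Sequence[GaussianFeature]] | None = None
    pixel_noise_sd: float = 0.01
    edge_noise_sd: float = 0.028
    clean_window: tuple[float, float] = CLEAN_WINDOW_NM
    sample_radius_px: int = 10
    image_shape: tuple[int, int] = (64, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes <= 0:
            raise ValueError("n_classes must be positive")
        if self.samples_per_class <= 0:
            raise ValueError("samples_per_class must be positive")
        if self.n_bands < 2:
            raise ValueError("n_bands must be at least 2")
        if not self.wavelength_end > self.wavelength_start:
            raise ValueError("wavelength axis must be increasing")
        if self.class_deltas is None:
            self.class_deltas = _default_class_deltas(self.n_classes)
        if len(self.class_deltas) != self.n_classes:
            raise ValueError(
                f"class_deltas must have exactly n_classes={self.n_classes} entries"
            )
        for c, w, a in self.shared_features:
            if not (np.isfinite(c) and np.isfinite(w) and np.isfinite(a)):
                raise ValueError("shared feature parameters must be finite")
            if w <= 0:
                raise ValueError("feature widths must be positive")
        for deltas in self.class_deltas:
            for c, w, a in deltas:
                if not (np.isfinite(c) and np.isfinite(w) and np.isfinite(a)):
                    raise ValueError("class delta parameters must be finite")
                if w <= 0:
                    raise ValueError("feature widths must be positive")
        if self.pixel_noise_sd < 0 or self.edge_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")

    @property
    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wavelength_start, self.wavelength_end, self.n_bands)


def well_separated_config(**overrides) -> SyntheticConfig:
    """Preset with large (~0.2) class amplitudes, for runs that must reach
    high accuracy deterministically; the default config keeps classes
    heavily overlapping instead."""
    n_classes = overrides.pop("n_classes", 12)
    centers = np.linspace(980.0, 1500.0, n_classes)
    deltas = [
        [(float(c), 45.0, 0.2 * (1 if k % 2 == 0 else -1))]
        for k, c in enumerate(centers)
    ]
    return SyntheticConfig(n_classes=n_classes, class_deltas=deltas, **overrides)


def _gaussian_sum(wl: np.ndarray, features: Sequence[GaussianFeature]) -> np.ndarray:
    out = np.zeros_like(wl)
    for center, width, amp in features:
        out += amp * np.exp(-0.5 * ((wl - center) / width) ** 2)
    return out


def _baseline(wl: np.ndarray) -> np.ndarray:
    # gentle increasing-then-flat reflectance level in roughly [0.25, 0.6]
    return 0.25 + 0.35 / (1.0 + np.exp(-(wl - 1050.0) / 150.0))


def make_class_profiles(config: SyntheticConfig) -> np.ndarray:
    """Noiseless endmember spectrum per class: baseline + shared features
    + that class's deltas, clipped to [0, 1]. Shape (n_classes, n_bands)."""
    wl = config.wavelengths
    base = _baseline(wl) + _gaussian_sum(wl, config.shared_features)
    profiles = np.empty((config.n_classes, config.n_bands))
    for k in range(config.n_classes):
        profiles[k] = base + _gaussian_sum(wl, config.class_deltas[k])
    return np.clip(profiles, 0.0, 1.0)


def _band_noise_sd(config: SyntheticConfig) -> np.ndarray:
    """Per-band noise sd: pixel noise everywhere, edge noise added in
    quadrature outside the clean window."""
    wl = config.wavelengths
    lo, hi = config.clean_window
    sd = np.full(config.n_bands, float(config.pixel_noise_sd))
    edge = (wl < lo) | (wl > hi)
    sd[edge] = np.sqrt(config.pixel_noise_sd**2 + config.edge_noise_sd**2)
    return sd


def simulate_spectra_table(config: SyntheticConfig) -> SpectraTable:
    """Sample-level spectra: each row is its class profile plus Gaussian
    noise (stronger outside the clean window). Bit-identical for one seed."""
    rng = np.random.default_rng(config.seed)
    profiles = make_class_profiles(config)
    sd = _band_noise_sd(config)
    n = config.n_classes * config.samples_per_class
    X = np.empty((n, config.n_bands))
    labels = np.empty(n, dtype=int)
    provenance = []
    row = 0
    for k in range(config.n_classes):
        noise = rng.normal(0.0, 1.0, (config.samples_per_class, config.n_bands)) * sd
        X[row:row + config.samples_per_class] = profiles[k] + noise
        labels[row:row + config.samples_per_class] = k
        provenance.extend(f"class{k}/sample{i}" for i in range(config.samples_per_class))
        row += config.samples_per_class
    return SpectraTable(X, config.wavelengths, labels=labels, provenance=provenance)


# count levels emulating a 16-bit line-scan camera
_WHITE_LEVEL = 3500.0
_DARK_LEVEL = 120.0
_BACKGROUND_REFLECTANCE = 0.03


def simulate_cube(
    config: SyntheticConfig, class_id: int
) -> tuple[SpectralCube, ReferencePair, np.ndarray]:
    """Raw-count cube of one disc-shaped bulb of class ``class_id`` on a dark
    background, with its white/dark reference frames and ground-truth mask.

    The disc carries the class spectrum re-encoded as counts through the
    inverse of the calibration relation, ``raw = R*(white - dark) + dark``,
    so calibrating the cube with its own references recovers reflectance.
    """
    if not 0 <= class_id < config.n_classes:
        raise ValueError(f"class_id {class_id} outside [0, {config.n_classes})")
    rows, cols = config.image_shape
    r = config.sample_radius_px
    cy, cx = rows / 2.0 - 0.5, cols / 2.0 - 0.5
    if r > min(cy, cx, rows - 1 - cy, cols - 1 - cx) + 0.5:
        raise ValueError(f"disc radius {r} does not fit in image {config.image_shape}")

    rng = np.random.default_rng((config.seed, class_id))
    profile = make_class_profiles(config)[class_id]

    yy, xx = np.mgrid[0:rows, 0:cols]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2

    sd = _band_noise_sd(config)
    refl = np.full((rows, cols, config.n_bands), _BACKGROUND_REFLECTANCE)
    refl[mask] = profile
    refl = refl + rng.normal(0.0, 1.0, refl.shape) * sd
    refl = np.clip(refl, 0.0, 1.2)

    # white tile counts droop slightly at the band edges, as real lamps do
    wl = config.wavelengths
    lamp = 1.0 - 0.1 * ((wl - wl.mean()) / (wl[-1] - wl[0])) ** 2
    white = np.broadcast_to(_WHITE_LEVEL * lamp, refl.shape).copy()
    dark = np.full(refl.shape, _DARK_LEVEL)

    raw = refl * (white - dark) + dark
    cube = SpectralCube(raw, wl, kind="raw_counts")
    return cube, ReferencePair(white=white, dark=dark), mask
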