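"""Colony-image wavelength pipeline: polar transform, angular boundary
profile and FFT wavelength in physical units.

A grayscale photograph of a roughly circular colony (brightfield
intensity as a surrogate for cell density) is resampled from Cartesian
to polar coordinates about the estimated colony centre.  The intensity
versus angle near the colony edge is a one-dimensional periodic signal;
its power spectrum gives the number of angular lobes ``m`` and hence a
characteristic wavelength ``lambda = 2*pi*r/m`` (arc length per lobe) at
the sampling radius ``r``, in centimetres.  Featureless colonies return
no wavelength.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .spectral_analysis import power_spectrum, dominant_wavelength

__all__ = [
    "ColonyImage",
    "AngularProfile",
    "estimate_center",
    "polar_transform",
    "boundary_profile",
    "colony_wavelength",
    "detect_colony_edge",
    "analyze_colony_image",
]

DEFAULT_N_RADII = 512
DEFAULT_N_ANGLES = 1024


@dataclass
class ColonyImage:
    """Grayscale intensity grid with a physical pixel size.

    ``pixels`` is row-major (row 0 at the top, as read from file);
    ``pixel_size_cm`` is the physical edge length of one pixel.
    """

    pixels: np.ndarray
    pixel_size_cm: float
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D grayscale grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.pixel_size_cm <= 0:
            raise ValueError("pixel_size_cm must be positive")

    @classmethod
    def from_file(cls, path, pixel_size_cm: float) -> "ColonyImage":
        """Read a PNG or TIFF image, converting to grayscale if needed."""
        img = Image.open(path)
        if img.mode not in ("L", "I", "I;16", "F"):
            img = img.convert("L")
        return cls(np.asarray(img, dtype=float), pixel_size_cm, str(path))

    def background_subtracted(self, border: int = 8) -> "ColonyImage":
        """Subtract the median intensity of a border frame of the image."""
        px = self.pixels
        frame = np.concatenate(
            [
                px[:border].ravel(),
                px[-border:].ravel(),
                px[:, :border].ravel(),
                px[:, -border:].ravel(),
            ]
        )
        return ColonyImage(
            px - np.median(frame), self.pixel_size_cm, self.provenance
        )

    def otsu_threshold(self) -> float:
        """Bimodal (Otsu) split of the intensity histogram."""
        return float(threshold_otsu(self.pixels))


@dataclass
class AngularProfile:
    """Intensity versus angle on a circle of fixed radius.

    Angles ascend, equally spaced in [0, 2*pi); ``radius_cm`` is the
    sampling radius in centimetres.
    """

    radius_cm: float
    angles: np.ndarray
    intensity: np.ndarray
    center_px: Tuple[float, float]

    def __post_init__(self) -> None:
        if self.angles.size < 64:
            raise ValueError("need at least 64 angular samples")
        spacing = np.diff(self.angles)
        if np.any(np.abs(spacing - spacing[0]) > 1e-12):
            raise ValueError("angles must be uniformly spaced")

    @property
    def arc_length_per_sample_cm(self) -> float:
        return 2.0 * np.pi * self.radius_cm / self.angles.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"angle": self.angles, "intensity": self.intensity})


def estimate_center(image: ColonyImage, threshold: float) -> Tuple[float, float]:
    """Intensity-weighted centroid (row, col) of pixels above threshold."""
    px = image.pixels
    mask = px > threshold
    if not mask.any():
        raise ValueError("no pixel above threshold; cannot locate colony")
    w = np.where(mask, px - threshold, 0.0)
    total = w.sum()
    rows, cols = np.mgrid[: px.shape[0], : px.shape[1]]
    return float((rows * w).sum() / total), float((cols * w).sum() / total)


def polar_transform(
    image: ColonyImage,
    center: Tuple[float, float],
    n_radii: int = DEFAULT_N_RADII,
    n_angles: int = DEFAULT_N_ANGLES,
) -> np.ndarray:
    """Resample the image onto a (radius x angle) grid about ``center``.

    Bilinear interpolation; radii run from 0 to the largest circle
    inscribed in the image around the centre, angles over [0, 2*pi).
    Returns an (n_radii, n_angles) array.
    """
    rows, cols = image.pixels.shape
    r0, c0 = center
    if not (0 <= r0 <= rows - 1 and 0 <= c0 <= cols - 1):
        raise ValueError(f"center {center} lies outside the image")
    r_max = min(r0, rows - 1 - r0, c0, cols - 1 - c0)
    radii = np.linspace(0.0, r_max, n_radii)
    angles = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    rr = radii[:, None]
    # image rows grow downward; theta measured from +x (columns) CCW
    sample_rows = r0 - rr * np.sin(angles)[None, :]
    sample_cols = c0 + rr * np.cos(angles)[None, :]
    return ndimage.map_coordinates(
        image.pixels, [sample_rows, sample_cols], order=1, mode="nearest"
    )


def _colony_radius_index(
    polar_grid: np.ndarray, edge_threshold: Optional[float] = None
) -> int:
    """Row index of the colony radius: the largest radius whose mean
    intensity over angle still exceeds the edge threshold."""
    ring_mean = polar_grid.mean(axis=1)
    if edge_threshold is None:
        lo, hi = ring_mean.min(), ring_mean.max()
        if hi - lo <= 0:
            raise ValueError("featureless polar grid; colony radius undetectable")
        edge_threshold = 0.5 * (lo + hi)
    above = np.flatnonzero(ring_mean > edge_threshold)
    if above.size == 0:
        raise ValueError("no radius exceeds the edge threshold")
    return int(above.max())


def boundary_profile(
    polar_grid: np.ndarray,
    radius_fraction: float,
    pixel_size_cm: float,
    center_px: Tuple[float, float] = (np.nan, np.nan),
    edge_threshold: Optional[float] = None,
    max_radius_px: Optional[float] = None,
) -> AngularProfile:
    """Intensity versus angle at a fraction of the detected colony radius.

    The colony radius is the largest radius whose angular mean intensity
    exceeds ``edge_threshold`` (default: midpoint of the ring-mean
    range).  ``max_radius_px`` is the physical radius of the polar
    grid's outermost row (defaults to ``n_radii - 1`` grid steps of one
    pixel, i.e. the grid was sampled on whole pixels).
    """
    if not 0 < radius_fraction <= 1:
        raise ValueError("radius_fraction must be in (0, 1]")
    n_radii, n_angles = polar_grid.shape
    edge_idx = _colony_radius_index(polar_grid, edge_threshold)
    row = int(round(edge_idx * radius_fraction))
    if max_radius_px is None:
        max_radius_px = n_radii - 1.0
    radius_px = max_radius_px * row / (n_radii - 1)
    angles = np.linspace(0.0, 2.0 * np.pi, n_angles, endpoint=False)
    return AngularProfile(
        radius_cm=float(radius_px * pixel_size_cm),
        angles=angles,
        intensity=polar_grid[row].astype(float),
        center_px=center_px,
    )


def colony_wavelength(
    profile: AngularProfile, prominence_threshold: float = 1.5
) -> Optional[float]:
    """Characteristic boundary wavelength in cm, or None.

    The angular intensity profile is normalised to its relative
    modulation and spectrally analysed; because the profile is periodic
    over the full circle, every DFT bin is an integer number of lobes
    ``m`` per revolution, and the wavelength is the arc length
    ``2*pi*r/m`` at the sampling radius.  Returns None when no spectral
    peak reaches the prominence threshold (featureless boundary).
    """
    intensity = profile.intensity
    mean = intensity.mean()
    if mean <= 0 or intensity.std() == 0:
        return None
    rel = intensity / mean - 1.0
    spec = power_spectrum(rel)
    wl_samples = dominant_wavelength(
        spec, prominence_threshold, max_wavelength=intensity.size / 2.0
    )
    if wl_samples is None:
        return None
    # a genuine lobed boundary concentrates power at its fundamental;
    # broadband noise spreads it thinly over all bins
    total = spec.power[1:].sum()
    k = int(round(intensity.size / wl_samples))
    if total <= 0 or spec.power[k] < 0.05 * total:
        return None
    m = k  # integer lobes per revolution
    if m < 2:
        return None
    return 2.0 * np.pi * profile.radius_cm / m


def analyze_colony_image(
    image: ColonyImage,
    radius_fraction: float = 0.95,
    n_radii: int = DEFAULT_N_RADII,
    n_angles: int = DEFAULT_N_ANGLES,
    prominence_threshold: float = 1.5,
    subtract_background: bool = True,
):
    """Full pipeline: centre, polar transform, edge profile, wavelength.

    Returns ``(profile, wavelength_cm)`` where ``wavelength_cm`` is None
    for a featureless boundary.
    """
    img = image.background_subtracted() if subtract_background else image
    thr = img.otsu_threshold()
    center = estimate_center(img, thr)
    polar = polar_transform(img, center, n_radii=n_radii, n_angles=n_angles)
    rows, cols = img.pixels.shape
    r_max = min(center[0], rows - 1 - center[0], center[1], cols - 1 - center[1])
    # edge level from the ring-mean midpoint, not Otsu: on a two-valued
    # histogram skimage's Otsu lands just above the background mode
    profile = boundary_profile(
        polar,
        radius_fraction,
        img.pixel_size_cm,
        center_px=center,
        edge_threshold=None,
        max_radius_px=r_max,
    )
    return profile, colony_wavelength(profile, prominence_threshold)


def detect_colony_edge(image: ColonyImage, threshold: float) -> np.ndarray:
    """Outer contour of the largest above-threshold component.

    Returns an (n, 2) array of subpixel (row, col) points ordered
    counterclockwise with respect to the image's x/y axes (columns
    right, rows up).
    """
    mask = image.pixels > threshold
    if not mask.any():
        raise ValueError("no pixel above threshold; empty mask")
    labels, n_labels = ndimage.label(mask)
    if n_labels > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_labels + 1))
        keep = 1 + int(np.argmax(sizes))
        mask = labels == keep
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("no contour found around the colony")
    contour = max(contours, key=len)
    # signed area in (col, row-up) coordinates; enforce CCW
    c = contour[:, 1]
    r = -contour[:, 0]
    area = 0.5 * np.sum(c * np.roll(r, -1) - np.roll(c, -1) * r)
    if area < 0:
        contour = contour[::-1]
    return contour
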