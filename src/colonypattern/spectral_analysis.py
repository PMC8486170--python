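"""Spatial power spectra, dominant wavelength and dynamical-phase labels.

A simulated colony profile (total cells ``x + y`` along the lattice) is
characterised by the discrete Fourier power spectrum of its
mean-subtracted values; peaks are scored by prominence
(``scipy.signal.find_peaks``) and a peak with prominence >= 1.5 marks a
periodic pattern whose wavelength is the inverse of the peak frequency,
in lattice units.

For phase classification the spectrum is taken of the *relative density
modulation* ``profile / mean(profile) - 1``, which makes the prominence
threshold meaningful across runs whose absolute density scale varies by
orders of magnitude: an essentially flat filled profile keeps all peak
powers far below 1, while a genuine periodic arrangement modulating the
density by tens of percent produces peak powers in the hundreds.

Phases:

Classification crosses the presence of a prominent peak with whether
the colony limited its own growth (the front stalled in the interior)
or swept the domain:

``traveling_front``
    no prominent spectral peak, colony still expanding or it already
    swept the whole domain — growth never limited itself;
``no_pattern``
    no prominent peak and the front stalled in the interior;
``standing_wave``
    prominent peak, colony swept the domain leaving a sustained
    stationary oscillation;
``damped_oscillation``
    prominent peak and self-limited growth: the inhibition is strong
    enough to stall the front near the inoculum, and the oscillation
    amplitude decays away from the seeding centre.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_prominences

from .simulator import Trajectory

__all__ = [
    "PowerSpectrum",
    "PhaseLabel",
    "power_spectrum",
    "dominant_wavelength",
    "classify_phase",
    "envelope_decay_ratio",
    "angular_boundary_radius",
    "PHASE_ORDER",
]

#: labels ordered from least to most patterned (used for consensus tie-breaks)
PHASE_ORDER = ("no_pattern", "traveling_front", "damped_oscillation", "standing_wave")

DEFAULT_PROMINENCE = 1.5
#: fraction of domain length the front must advance over the last quarter of
#: a run to still count as traveling
FRONT_GROWTH_FRACTION = 0.01
#: occupancy = profile above this fraction of its maximum; set above the
#: sub-percent leaked halo of stalled colonies (~6% of max) and below the
#: bulk plateau of swept ones (>~30% of max)
OCCUPANCY_FRACTION = 0.1
#: minimum relative modulation (std/mean) for a profile to carry a pattern
MIN_MODULATION_CV = 0.1
#: fraction of the half-domain the front must cover to count as having
#: swept the domain rather than self-limited its growth
SWEPT_FRACTION = 0.95


@dataclass
class PowerSpectrum:
    """One-sided power spectrum with prominence-scored peaks.

    ``peaks`` holds ``(frequency, power, prominence)`` for every local
    maximum of the power sequence (DC excluded); prominence is measured
    on the scale named in ``prominence_scale`` ("raw" power or "log10"
    decades).
    """

    frequencies: np.ndarray
    power: np.ndarray
    peaks: List[Tuple[float, float, float]]
    prominence_scale: str = "raw"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency": self.frequencies, "power": self.power})


@dataclass
class PhaseLabel:
    """Dynamical phase of a run, with the pattern wavelength if one exists."""

    label: str
    wavelength: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label not in PHASE_ORDER:
            raise ValueError(f"unknown phase label {self.label!r}")
        has_wl = self.wavelength is not None
        if has_wl != (self.label in ("standing_wave", "damped_oscillation")):
            raise ValueError("wavelength must be present exactly for patterned labels")


def power_spectrum(profile, prominence_scale: str = "raw") -> PowerSpectrum:
    """Power spectrum of a mean-subtracted 1D profile.

    Frequencies are in cycles per lattice site, non-negative only; power
    is the squared modulus of the DFT.  All interior local maxima of the
    power sequence are recorded with their prominences so callers can
    apply any threshold.
    """
    p = np.asarray(profile, dtype=float)
    if p.ndim != 1 or p.size < 8:
        raise ValueError("profile must be 1D with at least 8 samples")
    if not np.all(np.isfinite(p)):
        raise ValueError("profile contains non-finite values")
    spec = np.fft.rfft(p - p.mean())
    power = np.abs(spec) ** 2
    freqs = np.fft.rfftfreq(p.size, d=1.0)
    if prominence_scale == "raw":
        score = power
    elif prominence_scale == "log10":
        floor = power.max() * 1e-20 if power.max() > 0 else 1.0
        score = np.log10(np.maximum(power, floor))
    else:
        raise ValueError(f"unknown prominence scale {prominence_scale!r}")
    idx, _ = find_peaks(score[1:])  # DC bin excluded
    proms = peak_prominences(score[1:], idx)[0] if idx.size else np.array([])
    peaks = [
        (float(freqs[1:][i]), float(power[1:][i]), float(pr))
        for i, pr in zip(idx, proms)
    ]
    return PowerSpectrum(freqs, power, peaks, prominence_scale)


def dominant_wavelength(
    spectrum: PowerSpectrum,
    prominence_threshold: float = DEFAULT_PROMINENCE,
    max_wavelength: Optional[float] = None,
) -> Optional[float]:
    """Wavelength (1/frequency, lattice units) of the highest-power peak
    with prominence >= the threshold; None if no peak qualifies.

    ``max_wavelength`` optionally rejects peaks whose period is too long
    to represent a repeating pattern (e.g. envelope components of a
    localized profile).
    """
    qualifying = [
        p
        for p in spectrum.peaks
        if p[2] >= prominence_threshold
        and (max_wavelength is None or 1.0 / p[0] <= max_wavelength)
    ]
    if not qualifying:
        return None
    freq, _, _ = max(qualifying, key=lambda p: p[1])
    return 1.0 / freq


def _occupied_extent(profile: np.ndarray, center: int) -> float:
    """Largest distance (sites) from the centre to an occupied site."""
    if profile.max() <= 0:
        return 0.0
    occ = np.flatnonzero(profile > OCCUPANCY_FRACTION * profile.max())
    if occ.size == 0:
        return 0.0
    return float(max(occ.max() - center, center - occ.min()))


def _occupied_width(profile: np.ndarray) -> float:
    if profile.max() <= 0:
        return 0.0
    occ = np.flatnonzero(profile > OCCUPANCY_FRACTION * profile.max())
    return float(occ.max() - occ.min()) if occ.size else 0.0


def envelope_decay_ratio(profile: np.ndarray, center: int) -> Optional[float]:
    """First-period amplitude decay of the oscillation away from the centre.

    Measured on the prominences of the spatial maxima of the profile
    (prominence, not raw height, so a pattern riding on a sloping
    background is judged by its oscillation amplitude): on each side of
    the centre, the ratio of the second outward peak's prominence to the
    first's; the steeper (smaller) flank is returned.  None if no side
    has two maxima.  Diagnostic companion to :func:`classify_phase` —
    self-limited (damped) patterns decay much faster per period than
    domain-sweeping standing waves.
    """
    if profile.max() <= 0:
        return None
    idx, _ = find_peaks(profile, prominence=profile.max() * 1e-3)
    if idx.size < 2:
        return None
    proms = peak_prominences(profile, idx)[0]
    first_ratios = []
    for mask in (idx >= center, idx < center):
        side_idx = idx[mask]
        side_prom = proms[mask]
        order = np.argsort(np.abs(side_idx - center))
        seq = side_prom[order]
        if seq.size >= 2:
            first_ratios.append(seq[1] / seq[0])
    return float(min(first_ratios)) if first_ratios else None


def angular_boundary_radius(
    lattice,
    field: np.ndarray,
    n_bins: int = 72,
    occupancy_fraction: float = OCCUPANCY_FRACTION,
) -> np.ndarray:
    """Colony boundary radius versus angle on a 2D lattice.

    The occupied region is the set of nodes whose field value exceeds
    ``occupancy_fraction`` of the maximum; for each of ``n_bins`` equal
    angular sectors about the centre node, the largest occupied radius
    is returned (0 for empty sectors).  The variance of this radius
    profile quantifies angular symmetry breaking of the colony shape.
    """
    center = lattice.center_node()
    pos = lattice.positions - lattice.positions[center]
    theta = np.arctan2(pos[:, 1], pos[:, 0])
    radius = np.hypot(pos[:, 0], pos[:, 1])
    occupied = field > occupancy_fraction * field.max()
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    out = np.zeros(n_bins)
    for k in range(n_bins):
        sel = occupied & (theta >= edges[k]) & (theta < edges[k + 1])
        if sel.any():
            out[k] = radius[sel].max()
    return out


def classify_phase(
    trajectory: Trajectory,
    prominence_threshold: float = DEFAULT_PROMINENCE,
    prominence_scale: str = "raw",
    species: str = "total",
) -> PhaseLabel:
    """Label a finished 1D run by its final spatial organisation.

    The final total-cell profile (x + y by default; ``species`` may be
    "x", "y", "H" or "total") is normalised to its relative modulation
    ``p/mean(p) - 1`` and spectrally analysed; see the module docstring
    for the decision rules.
    """
    if len(trajectory.snapshots) < 2:
        raise ValueError("need at least 2 snapshots to classify a run")
    if trajectory.lattice.kind != "chain_1d":
        raise NotImplementedError("phase classification is defined on 1D runs")
    center = trajectory.lattice.center_node()
    n = trajectory.lattice.n_nodes

    def _profile(state):
        if species == "total":
            return state.total_cells()
        return getattr(state, species)

    final = _profile(trajectory.final_state)
    wavelength = None
    mean = final.mean()
    if mean > 0 and final.std() / mean >= MIN_MODULATION_CV:
        rel = final / mean - 1.0
        spec = power_spectrum(rel, prominence_scale=prominence_scale)
        width = _occupied_width(final)
        wavelength = dominant_wavelength(
            spec, prominence_threshold, max_wavelength=width / 2.0
        )
    # growth self-limitation over the last quarter of the saved snapshots
    k = max(1, (len(trajectory.snapshots) - 1) // 4)
    extent_then = _occupied_extent(_profile(trajectory.snapshots[-1 - k][1]), center)
    extent_now = _occupied_extent(final, center)
    swept = extent_now >= SWEPT_FRACTION * max(center, n - 1 - center)
    growing = (extent_now - extent_then) > FRONT_GROWTH_FRACTION * n
    if wavelength is not None:
        if swept or growing:
            return PhaseLabel("standing_wave", wavelength)
        return PhaseLabel("damped_oscillation", wavelength)
    if swept or growing:
        return PhaseLabel("traveling_front")
    return PhaseLabel("no_pattern")
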