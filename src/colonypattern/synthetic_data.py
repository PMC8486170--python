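"""Synthetic fixtures with closed-form ground truth.

Because the study's colony photographs are not deposited, every stage of
the image pipeline is exercised on generated data: lobed colony images
whose boundary radius is ``R(theta) = R0 + A*cos(m*theta)`` (so the
angular wavelength at radius r is exactly ``2*pi*r/m``), 1D profiles
with known sinusoidal content, and ready-to-run simulation configs for
the reference regimes.  All generators are deterministic under a fixed
seed and emit their ground truth alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .colony_image_analysis import ColonyImage
from .model_core import ModelParams

__all__ = [
    "SyntheticColonySpec",
    "generate_colony_image",
    "generate_test_profile",
    "make_fixture_configs",
]


@dataclass(frozen=True)
class SyntheticColonySpec:
    """Parameters of a synthetic lobed colony image.

    A pixel belongs to the colony when its distance r from the centre
    satisfies ``r <= base_radius_cm + lobe_amplitude_cm*cos(n_lobes*theta)``;
    ``n_lobes = 0`` gives a plain disk.  Defaults emulate the study's
    scale: a ~0.4 cm colony with 12 lobes gives a boundary wavelength of
    about 0.2 cm.
    """

    image_size_px: Tuple[int, int] = (512, 512)
    pixel_size_cm: float = 0.0025
    center_px: Optional[Tuple[float, float]] = None
    base_radius_cm: float = 0.4
    n_lobes: int = 12
    lobe_amplitude_cm: float = 0.04
    interior_intensity: float = 200.0
    background_intensity: float = 30.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lobes < 0:
            raise ValueError("n_lobes must be >= 0")
        if self.base_radius_cm <= 0 or self.lobe_amplitude_cm < 0:
            raise ValueError("radii must be positive")
        rows, cols = self.image_size_px
        r0, c0 = self.center
        reach_px = (self.base_radius_cm + self.lobe_amplitude_cm) / self.pixel_size_cm
        if (
            r0 - reach_px < 0
            or c0 - reach_px < 0
            or r0 + reach_px > rows - 1
            or c0 + reach_px > cols - 1
        ):
            raise ValueError("colony geometry exceeds the image")

    @property
    def center(self) -> Tuple[float, float]:
        if self.center_px is not None:
            return self.center_px
        rows, cols = self.image_size_px
        return ((rows - 1) / 2.0, (cols - 1) / 2.0)

    def boundary_wavelength_cm(self, radius_fraction: float = 1.0) -> Optional[float]:
        """Exact arc-length wavelength at a fraction of the base radius."""
        if self.n_lobes == 0:
            return None
        return 2.0 * np.pi * self.base_radius_cm * radius_fraction / self.n_lobes

    def ground_truth(self) -> dict:
        return {
            "center_px": list(self.center),
            "base_radius_cm": self.base_radius_cm,
            "n_lobes": self.n_lobes,
            "lobe_amplitude_cm": self.lobe_amplitude_cm,
            "boundary_wavelength_cm": self.boundary_wavelength_cm(),
            "pixel_size_cm": self.pixel_size_cm,
        }


def generate_colony_image(spec: SyntheticColonySpec) -> ColonyImage:
    """Render the lobed colony of ``spec`` with additive Gaussian noise."""
    rows, cols = spec.image_size_px
    r0, c0 = spec.center
    rr, cc = np.mgrid[:rows, :cols].astype(float)
    # theta measured from +x (columns) CCW, rows growing downward
    theta = np.arctan2(r0 - rr, cc - c0)
    dist_cm = np.hypot(rr - r0, cc - c0) * spec.pixel_size_cm
    if spec.n_lobes == 0:  # plain disk
        radius = spec.base_radius_cm
    else:
        radius = spec.base_radius_cm + spec.lobe_amplitude_cm * np.cos(
            spec.n_lobes * theta
        )
    px = np.where(dist_cm <= radius, spec.interior_intensity, spec.background_intensity)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        px = px + rng.normal(0.0, spec.noise_sd, size=px.shape)
    return ColonyImage(
        px, spec.pixel_size_cm, provenance=f"synthetic:{asdict(spec)}"
    )


def generate_test_profile(
    length: int,
    components: Sequence[Tuple[float, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Sum of sinusoids ``amplitude*sin(2*pi*i/period)`` plus noise."""
    if length < 8:
        raise ValueError("length must be >= 8")
    i = np.arange(length, dtype=float)
    profile = np.zeros(length)
    for period, amplitude in components:
        if not 0 < period <= length / 2:
            raise ValueError(f"period {period} invalid for length {length}")
        profile += amplitude * np.sin(2.0 * np.pi * i / period)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        profile = profile + rng.normal(0.0, noise_sd, size=length)
    return profile


def save_colony_png(image: ColonyImage, spec: SyntheticColonySpec, path) -> None:
    """Write the image as 8-bit PNG with a ground-truth YAML sidecar."""
    px = np.clip(image.pixels, 0, 255).astype(np.uint8)
    Image.fromarray(px, mode="L").save(path)
    sidecar = Path(path).with_suffix(".truth.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(spec.ground_truth(), fh, sort_keys=False)


def make_fixture_configs(out_dir) -> List[Path]:
    """Emit ready-to-run YAML configs for the reference experiments.

    Covers the three 1D reference regimes, the reduced 2D run, a reduced
    sweep, and three synthetic colony images (0, 6, 12 lobes).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    anchors = {
        "run_traveling_front": (-1.0, -1.0),
        "run_standing_wave": (-5.0, -4.0),
        "run_damped_oscillation": (-6.0, -6.0),
    }
    for name, (ld, lh) in anchors.items():
        params = ModelParams().with_log10(delta_H=ld, H_c=lh)
        cfg = {
            "kind": "simulation",
            "lattice": {"kind": "chain_1d", "n_sites": 400},
            "params": params.to_dict(),
            "n_iter": 20000,
            "save_every": 200,
        }
        written.append(_write(out / f"{name}.yaml", cfg))

    params_2d = ModelParams(mu=2.0, H_c=5.0, delta_H=0.005)
    cfg_2d = {
        "kind": "simulation",
        "lattice": {"kind": "hex_2d", "width": 100, "height": 100},
        "params": params_2d.to_dict(),
        "n_iter": 12000,
        "save_every": 400,
    }
    written.append(_write(out / "run_2d_symmetry_breaking.yaml", cfg_2d))

    cfg_sweep = {
        "kind": "sweep",
        "log10_delta_H_range": [-6.0, -1.0, 11],
        "log10_H_c_range": [-6.0, -1.0, 11],
        "replicates": 2,
        "n_sites": 400,
        "n_iter": 20000,
        "base_params": ModelParams().to_dict(),
    }
    written.append(_write(out / "sweep_reduced.yaml", cfg_sweep))

    for n_lobes in (0, 6, 12):
        spec = SyntheticColonySpec(n_lobes=n_lobes)
        cfg = {"kind": "synthetic_colony", **_plain(asdict(spec))}
        written.append(_write(out / f"colony_{n_lobes}_lobes.yaml", cfg))
    return written


def _plain(d: dict) -> dict:
    return {
        k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()
    }


def _write(path: Path, cfg: dict) -> Path:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return path
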