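"""Phase/wavelength diagram over the (delta_H, H_c) plane.

Reproduces the parameter-sensitivity experiment: a grid of
(log10 delta_H, log10 H_c) cells, each simulated in replicate on a 1D
domain and classified into a dynamical phase with a characteristic
wavelength.  The full-scale experiment is 51 x 51 cells x 5 replicates
of a 400-site domain over 20 000 iterations (13 005 runs); reduced grids
are used for routine checks.

Every run's seed derives deterministically from the master seed and the
cell/replicate indices, so the diagram is reproducible bit for bit and
cells may be computed in any order or in parallel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .lattice import build_lattice_1d
from .model_core import ModelParams
from .simulator import run_simulation, IntegrationBlowupError
from .spectral_analysis import classify_phase, PHASE_ORDER

__all__ = ["SweepSpec", "PhaseDiagram", "run_sweep", "derive_seed"]


@dataclass(frozen=True)
class SweepSpec:
    """Grid specification for a (delta_H, H_c) sweep.

    Ranges are (min, max, count) in log10; the grid axis limits default
    to [-6, -1] on both axes, which places the three reference regimes
    inside the diagram (a reconstruction — the original axis limits are
    not printed).
    """

    log10_delta_H_range: Tuple[float, float, int] = (-6.0, -1.0, 51)
    log10_H_c_range: Tuple[float, float, int] = (-6.0, -1.0, 51)
    replicates: int = 5
    base_params: ModelParams = field(default_factory=ModelParams)
    n_sites: int = 400
    n_iter: int = 20_000
    master_seed: int = 0
    prominence_threshold: float = 1.5

    def __post_init__(self) -> None:
        for rng in (self.log10_delta_H_range, self.log10_H_c_range):
            if len(rng) != 3 or rng[2] < 2:
                raise ValueError("range must be (min, max, count>=2)")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def delta_H_values(self) -> np.ndarray:
        lo, hi, n = self.log10_delta_H_range
        return np.linspace(lo, hi, int(n))

    @property
    def H_c_values(self) -> np.ndarray:
        lo, hi, n = self.log10_H_c_range
        return np.linspace(lo, hi, int(n))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["base_params"] = self.base_params.to_dict()
        return d


def derive_seed(master_seed: int, i: int, j: int, replicate: int) -> int:
    """Deterministic per-run seed from the master seed and indices."""
    ss = np.random.SeedSequence([int(master_seed), int(i), int(j), int(replicate)])
    return int(ss.generate_state(1, dtype=np.uint32)[0])


@dataclass
class PhaseDiagram:
    """Per-cell phase labels and wavelengths plus replicate consensus.

    ``table`` has one row per (cell, replicate); ``consensus`` one row
    per cell with the modal label (ties resolve toward the
    more-patterned label, ordering :data:`PHASE_ORDER`) and the median
    wavelength of patterned replicates.
    """

    spec: SweepSpec
    table: pd.DataFrame

    @property
    def consensus(self) -> pd.DataFrame:
        rows = []
        for (i, j), grp in self.table.groupby(["i", "j"], sort=True):
            labels = grp["label"].tolist()
            # modal label; ties resolve to the more-patterned candidate
            counts = {lab: labels.count(lab) for lab in set(labels)}
            top = max(counts.values())
            winner = max(
                (lab for lab, c in counts.items() if c == top),
                key=PHASE_ORDER.index,
            )
            wavelengths = grp["wavelength"].dropna()
            rows.append(
                {
                    "i": i,
                    "j": j,
                    "log10_delta_H": grp["log10_delta_H"].iloc[0],
                    "log10_H_c": grp["log10_H_c"].iloc[0],
                    "label": winner,
                    "median_wavelength": (
                        float(wavelengths.median()) if len(wavelengths) else np.nan
                    ),
                }
            )
        return pd.DataFrame(rows)

    def consensus_grid(self) -> np.ndarray:
        """Consensus labels as an (n_delta_H, n_H_c) object array."""
        cons = self.consensus
        ni = int(self.spec.log10_delta_H_range[2])
        nj = int(self.spec.log10_H_c_range[2])
        grid = np.empty((ni, nj), dtype=object)
        for _, row in cons.iterrows():
            grid[int(row["i"]), int(row["j"])] = row["label"]
        return grid

    def cell_nearest(self, log10_delta_H: float, log10_H_c: float) -> pd.Series:
        """Consensus row of the grid cell nearest a (log10, log10) point."""
        i = int(np.argmin(np.abs(self.spec.delta_H_values - log10_delta_H)))
        j = int(np.argmin(np.abs(self.spec.H_c_values - log10_H_c)))
        cons = self.consensus
        return cons[(cons["i"] == i) & (cons["j"] == j)].iloc[0]

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "sweep_runs.tsv", sep="\t", index=False)
        self.consensus.to_csv(out / "sweep_consensus.tsv", sep="\t", index=False)

    def plot(self, ax=None):
        """Heat map of the consensus phases (wavelength as annotation)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        order = {lab: k for k, lab in enumerate(PHASE_ORDER)}
        grid = self.consensus_grid()
        img = np.vectorize(order.get)(grid).astype(float)
        ax.imshow(
            img.T,
            origin="lower",
            aspect="auto",
            extent=[
                self.spec.delta_H_values[0],
                self.spec.delta_H_values[-1],
                self.spec.H_c_values[0],
                self.spec.H_c_values[-1],
            ],
            vmin=0,
            vmax=len(PHASE_ORDER) - 1,
            cmap="viridis",
        )
        ax.set_xlabel(r"$\log_{10}\,\delta_H$")
        ax.set_ylabel(r"$\log_{10}\,H_c$")
        return ax


def run_sweep(spec: SweepSpec, progress: bool = False) -> PhaseDiagram:
    """Run and classify every (cell, replicate) of the sweep.

    A run that blows up numerically is recorded with label
    ``"failed"`` for that replicate instead of aborting the sweep.
    """
    lattice = build_lattice_1d(spec.n_sites)
    rows = []
    dvals, hvals = spec.delta_H_values, spec.H_c_values
    total = len(dvals) * len(hvals) * spec.replicates
    done = 0
    for i, ld in enumerate(dvals):
        for j, lh in enumerate(hvals):
            params = spec.base_params.with_log10(delta_H=ld, H_c=lh)
            for r in range(spec.replicates):
                seed = derive_seed(spec.master_seed, i, j, r)
                try:
                    traj = run_simulation(
                        lattice, params, n_iter=spec.n_iter, seed=seed
                    )
                    phase = classify_phase(
                        traj, prominence_threshold=spec.prominence_threshold
                    )
                    label, wl = phase.label, phase.wavelength
                except IntegrationBlowupError:
                    label, wl = "failed", None
                rows.append(
                    {
                        "i": i,
                        "j": j,
                        "log10_delta_H": ld,
                        "log10_H_c": lh,
                        "replicate": r,
                        "seed": seed,
                        "label": label,
                        "wavelength": wl,
                    }
                )
                done += 1
            if progress:
                print(f"\rsweep {done}/{total}", end="", flush=True)
    if progress:
        print()
    return PhaseDiagram(spec=spec, table=pd.DataFrame(rows))
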