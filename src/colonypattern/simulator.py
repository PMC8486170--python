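"""Explicit-Euler integration of the reaction-diffusion system on a lattice.

Runs start from a small random inoculum at the centre of the domain
(3 sites on a chain, a Euclidean disc of radius 10 on a hexagonal patch)
with ``x = 0.05 + U(0, 0.05)`` per seeded site and ``y = H = 0``
everywhere, and integrate with time step ``dt`` for a fixed budget of
iterations (default 20 000, by which the patterns studied here have
stabilised).  Only the active cells and the signal diffuse; the elongated
cells are immobile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from .lattice import Lattice, build_lattice_1d, build_lattice_hex, nodes_within_distance
from .model_core import ModelParams

__all__ = [
    "StateField",
    "Trajectory",
    "IntegrationBlowupError",
    "seed_initial_state",
    "euler_step",
    "run_simulation",
]

log = logging.getLogger(__name__)

SEED_RADIUS_2D = 10.0  # Euclidean radius of the 2D inoculum, in site spacings
CLAMP_TOL = 1e-12  # undershoot below -CLAMP_TOL is reported, not silent


class IntegrationBlowupError(RuntimeError):
    """Non-finite values appeared during integration."""

    def __init__(self, step: int):
        super().__init__(f"integration produced non-finite values at step {step}")
        self.step = step


@dataclass
class StateField:
    """Per-node fields at one time point."""

    x: np.ndarray
    y: np.ndarray
    H: np.ndarray
    t: float = 0.0
    step: int = 0

    def copy(self) -> "StateField":
        return StateField(self.x.copy(), self.y.copy(), self.H.copy(), self.t, self.step)

    def total_cells(self) -> np.ndarray:
        return self.x + self.y


@dataclass
class Trajectory:
    """Snapshots of a run plus everything needed to reproduce it."""

    snapshots: List[Tuple[int, StateField]]
    params: ModelParams
    lattice: Lattice
    seed: Optional[int]
    min_before_clamp: float = 0.0  # most negative value any field reached

    @property
    def final_state(self) -> StateField:
        return self.snapshots[-1][1]

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = {
            "params": self.params.to_dict(),
            "lattice": {"kind": self.lattice.kind, "shape": list(self.lattice.shape)},
            "seed": self.seed,
            "snapshots": [int(s) for s, _ in self.snapshots],
            "min_before_clamp": float(self.min_before_clamp),
        }
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
        for step, state in self.snapshots:
            pd.DataFrame(
                {
                    "node": np.arange(state.x.size),
                    "x": state.x,
                    "y": state.y,
                    "H": state.H,
                }
            ).to_csv(out / f"snapshot_{step:08d}.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, in_dir) -> "Trajectory":
        src = Path(in_dir)
        with open(src / "manifest.yaml") as fh:
            manifest = yaml.safe_load(fh)
        params = ModelParams.from_dict(manifest["params"])
        kind = manifest["lattice"]["kind"]
        shape = manifest["lattice"]["shape"]
        lattice = (
            build_lattice_1d(shape[0])
            if kind == "chain_1d"
            else build_lattice_hex(*shape)
        )
        snapshots = []
        for step in manifest["snapshots"]:
            df = pd.read_csv(src / f"snapshot_{step:08d}.tsv", sep="\t")
            snapshots.append(
                (
                    step,
                    StateField(
                        df["x"].to_numpy(),
                        df["y"].to_numpy(),
                        df["H"].to_numpy(),
                        t=step * params.dt,
                        step=step,
                    ),
                )
            )
        return cls(
            snapshots=snapshots,
            params=params,
            lattice=lattice,
            seed=manifest["seed"],
            min_before_clamp=manifest.get("min_before_clamp", 0.0),
        )


def seed_initial_state(lattice: Lattice, seed: int) -> StateField:
    """Central inoculum: x = 0.05 + U(0, 0.05) on the seeded sites.

    On a chain the seeded sites are the centre node and its two
    neighbours; on a hexagonal patch, every node within Euclidean
    distance :data:`SEED_RADIUS_2D` of the centre node.  y and H start at
    zero.  Deterministic given ``seed``.
    """
    n = lattice.n_nodes
    center = lattice.center_node()
    if lattice.kind == "chain_1d":
        if n < 3:
            raise ValueError("chain too small for a 3-site inoculum")
        seeded = np.array([center - 1, center, center + 1])
    else:
        w, h = lattice.shape
        if min(w, h) < 2 * SEED_RADIUS_2D + 1:
            raise ValueError(
                f"hex patch {w}x{h} cannot contain a radius-"
                f"{SEED_RADIUS_2D:g} inoculum"
            )
        seeded = np.array(sorted(nodes_within_distance(lattice, center, SEED_RADIUS_2D)))
    rng = np.random.default_rng(seed)
    x = np.zeros(n)
    x[seeded] = 0.05 + rng.uniform(0.0, 0.05, size=seeded.size)
    return StateField(x=x, y=np.zeros(n), H=np.zeros(n), t=0.0, step=0)


def euler_step(state: StateField, params: ModelParams, lattice: Lattice) -> StateField:
    """One explicit Euler step; returns a new StateField.

    Reference single-step entry point; :func:`run_simulation` uses an
    equivalent in-place loop.
    """
    new = state.copy()
    mn = _step_inplace(new.x, new.y, new.H, params, lattice.laplacian_matrix())
    if mn < -CLAMP_TOL:
        log.warning("clamped negative undershoot %.3e at step %d", mn, state.step + 1)
    if not (np.isfinite(new.x).all() and np.isfinite(new.y).all() and np.isfinite(new.H).all()):
        raise IntegrationBlowupError(state.step + 1)
    new.t = state.t + params.dt
    new.step = state.step + 1
    return new


def _step_inplace(x, y, H, params: ModelParams, lap) -> float:
    """Advance (x, y, H) by one Euler step in place.

    Returns the most negative value reached before clamping (0.0 if none).
    """
    dt = params.dt
    # overflow here surfaces as an IntegrationBlowupError via the callers'
    # finiteness checks, so the numpy warnings are noise
    with np.errstate(over="ignore", invalid="ignore"):
        # Phi = H^n / (H_c + H^n): H_c is the Hill activation coefficient
        Hn = H * H if params.n_hill == 2 else H ** params.n_hill
        phi = Hn / (params.H_c + Hn)
        diff_flux = params.kappa * phi * x
        rev_flux = params.nu * y
        dH = params.D_H * (lap @ H) + params.alpha * (x + y) - params.delta_H * H
        dx = (
            params.D_x * (lap @ x)
            + params.mu * x * (1.0 - x - y - phi)
            - diff_flux
            + rev_flux
        )
        dy = diff_flux - rev_flux
        x += dt * dx
        y += dt * dy
        H += dt * dH
    mn = min(float(x.min()), float(y.min()), float(H.min()))
    if mn < 0.0:
        np.maximum(x, 0.0, out=x)
        np.maximum(y, 0.0, out=y)
        np.maximum(H, 0.0, out=H)
    return min(mn, 0.0)


def run_simulation(
    lattice: Lattice,
    params: ModelParams,
    n_iter: int = 20_000,
    seed: int = 0,
    save_every: int = 200,
    initial_state: Optional[StateField] = None,
    stop_tol: Optional[float] = None,
) -> Trajectory:
    """Seed and integrate, saving a snapshot every ``save_every`` steps.

    Parameters
    ----------
    n_iter
        Fixed iteration budget (default 20 000).
    initial_state
        Start from this state instead of the random inoculum (used for
        controlled symmetric runs); ``seed`` is then ignored.
    stop_tol
        Optional early stop when the max-abs per-step change of every
        field falls below this value; off by default.
    """
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    if initial_state is not None:
        state = initial_state.copy()
        seed_used = None
    else:
        state = seed_initial_state(lattice, seed)
        seed_used = seed
    lap = lattice.laplacian_matrix()
    snapshots = [(0, state.copy())]
    x, y, H = state.x, state.y, state.H
    min_seen = 0.0
    check_every = max(1, min(save_every, 200))
    for step in range(1, n_iter + 1):
        if stop_tol is not None:
            x_prev, y_prev, H_prev = x.copy(), y.copy(), H.copy()
        mn = _step_inplace(x, y, H, params, lap)
        min_seen = min(min_seen, mn)
        if step % check_every == 0 or step == n_iter:
            if not np.isfinite(x).all() or not np.isfinite(H).all():
                raise IntegrationBlowupError(step)
        if step % save_every == 0 or step == n_iter:
            snapshots.append(
                (step, StateField(x.copy(), y.copy(), H.copy(), step * params.dt, step))
            )
        if stop_tol is not None:
            delta = max(
                np.abs(x - x_prev).max(),
                np.abs(y - y_prev).max(),
                np.abs(H - H_prev).max(),
            )
            if delta < stop_tol:
                if snapshots[-1][0] != step:
                    snapshots.append(
                        (step, StateField(x.copy(), y.copy(), H.copy(), step * params.dt, step))
                    )
                break
    if min_seen < -CLAMP_TOL:
        log.warning("run clamped negative undershoot down to %.3e", min_seen)
    return Trajectory(
        snapshots=snapshots,
        params=params,
        lattice=lattice,
        seed=seed_used,
        min_before_clamp=min_seen,
    )
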