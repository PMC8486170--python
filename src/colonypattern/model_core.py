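"""Local (well-mixed) kinetics of the three-species lateral-inhibition model.

The model couples an actively dividing cell population ``x``, a
differentiated elongated population ``y`` that neither divides nor moves,
and a fast-diffusing quorum-sensing signal ``H`` (a homoserine lactone)
produced by both populations.  The reaction part of the system, with
diffusion excluded, is::

    dx/dt = mu * x * (1 - x - y - Phi(H)) - kappa * Phi(H) * x + nu * y
    dy/dt = kappa * Phi(H) * x - nu * y
    dH/dt = alpha * (x + y) - delta_H * H

Growth of ``x`` is logistic toward the shared carrying capacity, further
suppressed by the signal through ``Phi`` inside the logistic bracket;
differentiation x -> y proceeds at rate ``kappa * Phi(H)`` and reverts at
the small linear rate ``nu``; the signal is produced at rate ``alpha``
per unit total cell density and decays exponentially at rate ``delta_H``.

Signal-dependent gene regulation is a Hill function with exponent ``n``
(default 2).  The model parameterizes it through the activation
coefficient ``H_c`` (units: signal^n), i.e.::

    Phi(H) = H^n / (H_c + H^n)

so the semi-activation concentration is ``H_c**(1/n)``.  Both Hill
conventions are standard; :func:`hill_activation` takes the
semi-activation concentration directly and the model feeds it
``H_c**(1/n)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, replace
from typing import Optional

import numpy as np
from scipy.optimize import brentq
import yaml

__all__ = [
    "ModelParams",
    "LocalState",
    "InvalidParameterError",
    "hill_activation",
    "reaction_terms",
    "homogeneous_steady_state",
]


class InvalidParameterError(ValueError):
    """A kinetic parameter or input violates the model's domain."""


@dataclass(frozen=True)
class ModelParams:
    """Kinetic and transport constants plus integration settings.

    Units: densities are in carrying-capacity units, lengths in lattice
    sites, time in model time units.  Diffusion coefficients are
    lattice-length^2 / time.  ``H_c`` is the Hill activation coefficient
    in units of signal^n_hill (semi-activation concentration
    ``H_c**(1/n_hill)``).

    Defaults are the base parameter set of the simulation studies
    (``D_x = 0.005``, ``D_H = 1e3 * D_x``, ``alpha = 2``, ``mu = 8``,
    ``nu = 0.001``, ``kappa = 0.1``, Hill exponent 2, Euler step
    ``dt = 0.01``) with the signal decay and threshold of the
    standing-wave regime (``delta_H = 1e-5``, ``H_c = 1e-4``).
    """

    D_x: float = 0.005
    D_H: float = 5.0
    mu: float = 8.0
    alpha: float = 2.0
    delta_H: float = 1e-5
    H_c: float = 1e-4
    n_hill: int = 2
    nu: float = 0.001
    kappa: float = 0.1
    dt: float = 0.01

    def __post_init__(self) -> None:
        positive = {
            "D_x": self.D_x,
            "D_H": self.D_H,
            "mu": self.mu,
            "alpha": self.alpha,
            "delta_H": self.delta_H,
            "H_c": self.H_c,
            "nu": self.nu,
            "kappa": self.kappa,
            "dt": self.dt,
        }
        for name, value in positive.items():
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"{name} must be strictly positive, got {value!r}"
                )
        if int(self.n_hill) != self.n_hill or self.n_hill < 1:
            raise InvalidParameterError(
                f"n_hill must be an integer >= 1, got {self.n_hill!r}"
            )
        if self.D_H < self.D_x:
            # long-range inhibition requires the signal to outrun the cells
            warnings.warn(
                "D_H < D_x: the signal diffuses slower than the active cells, "
                "which removes the long-range inhibition needed for patterning",
                stacklevel=2,
            )

    @property
    def hill_semiactivation(self) -> float:
        """Signal concentration at which Phi = 1/2."""
        return self.H_c ** (1.0 / self.n_hill)

    def with_log10(self, **kwargs: float) -> "ModelParams":
        """Copy with the named parameters set from log10 values
        (e.g. ``with_log10(delta_H=-5, H_c=-4)``)."""
        return replace(self, **{k: 10.0 ** v for k, v in kwargs.items()})

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class LocalState:
    """Per-site densities: active cells x, elongated cells y, signal H."""

    x: float
    y: float
    H: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0 or self.H < 0:
            raise InvalidParameterError(
                f"densities and signal must be non-negative, got {self}"
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.H])


def hill_activation(H, H_half: float, n_hill: int = 2):
    """Hill activation ``Phi(H) = H^n / (H_half^n + H^n)``.

    ``H_half`` is the semi-activation concentration: monotone
    non-decreasing in ``H`` with ``Phi(0) = 0``, ``Phi(H_half) = 1/2``
    and ``Phi -> 1`` as ``H -> inf``.  Accepts scalars or arrays in
    ``H``.
    """
    if H_half <= 0:
        raise InvalidParameterError(f"H_half must be positive, got {H_half!r}")
    if n_hill < 1:
        raise InvalidParameterError(f"n_hill must be >= 1, got {n_hill!r}")
    H = np.asarray(H, dtype=float)
    if np.any(H < 0):
        raise InvalidParameterError("H must be non-negative")
    # ratio form is robust for H >> H_half and H << H_half alike
    r = (H / H_half) ** n_hill
    out = r / (1.0 + r)
    return float(out) if out.ndim == 0 else out


def reaction_terms(state, params: ModelParams):
    """Reaction rates (dx/dt, dy/dt, dH/dt) with diffusion excluded.

    ``state`` may be a :class:`LocalState` or a triple of arrays
    ``(x, y, H)``; arrays are broadcast elementwise, which is how the
    spatial integrator uses this function.
    """
    if isinstance(state, LocalState):
        x, y, H = state.x, state.y, state.H
    else:
        x, y, H = state
    phi = hill_activation(H, params.hill_semiactivation, params.n_hill)
    diff_flux = params.kappa * phi * x
    rev_flux = params.nu * y
    dx = params.mu * x * (1.0 - x - y - phi) - diff_flux + rev_flux
    dy = diff_flux - rev_flux
    dH = params.alpha * (x + y) - params.delta_H * H
    return dx, dy, dH


def homogeneous_steady_state(params: ModelParams) -> Optional[LocalState]:
    """Nontrivial (x > 0) fixed point of the well-mixed kinetics, or None.

    At a steady state with ``x > 0`` the equations reduce to a single
    scalar condition on the total density ``s = x + y``::

        s = 1 - Phi(alpha * s / delta_H)

    (from d(x+y)/dt = 0 and dH/dt = 0), after which ``y = kappa*Phi*x/nu``
    and ``H = alpha*s/delta_H`` follow algebraically.  The scalar
    equation is solved by bracketing root finding; the left side is
    increasing and the right side decreasing in ``s``, so the root in
    (0, 1] is unique.
    """
    K = params.hill_semiactivation
    phi = lambda H: hill_activation(H, K, params.n_hill)
    f = lambda s: s - 1.0 + phi(params.alpha * s / params.delta_H)
    lo, hi = 1e-15, 1.0
    if f(lo) >= 0 or f(hi) < 0:
        if abs(f(hi)) < 1e-12:  # Phi(alpha/delta_H) == 0 edge: s* = 1
            s = 1.0
        else:
            return None
    else:
        s = brentq(f, lo, hi, xtol=1e-16, rtol=8.9e-16)
    H = params.alpha * s / params.delta_H
    ratio = params.kappa * phi(H) / params.nu  # y / x at stationarity
    x = s / (1.0 + ratio)
    y = s - x
    state = LocalState(x=max(x, 0.0), y=max(y, 0.0), H=H)
    resid = np.abs(reaction_terms(state, params))
    if float(np.max(resid)) > 1e-8 or state.x <= 0:
        return None
    return state
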