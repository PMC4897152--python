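"""Derived haemodynamic quantities: flux, wall shear stress, stream function.

All quantities are evaluated in the transformed rectangle, so the radial
integrals pick up the metric factor ``h(z)^2``:

* volumetric flux       ``Q(z)   = 2 pi h^2 int_0^1 x u dx``
* wall shear stress     ``tau(z) = -(mu / h) du/dx |_{x=1}``,
  discretized with the one-sided difference ``-(mu/h)(u_N - u_{N-1})/dx``
* Stokes stream function ``psi(x, z) = h^2 int_0^x x' u dx'`` so that
  ``u = (1/r) dpsi/dr``; psi vanishes on the axis and
  ``2 pi psi(1, z) = Q(z)`` exactly (shared trapezoidal quadrature).

Quadrature is the trapezoidal rule throughout, matching the discrete flux
definition of the scheme, so the flux/stream-function identity holds to
rounding error rather than merely to quadrature accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .geometry import StenosisGeometry
from .solver import FlowState, Grid, _check_compat

__all__ = [
    "ObservableSeries",
    "stream_function",
    "flow_rate",
    "wall_shear_stress",
    "profile",
    "compute_observables",
]


def stream_function(state: FlowState, grid: Grid, geom: StenosisGeometry) -> np.ndarray:
    """Stokes stream function psi on the full (M+1, N+1) lattice."""
    _check_compat(grid, geom)
    h = geom.wall_radius(grid.z)
    integrand = grid.x[None, :] * state.u
    return h[:, None] ** 2 * cumulative_trapezoid(
        integrand, dx=grid.dx, initial=0.0, axis=1
    )


def flow_rate(state: FlowState, grid: Grid, geom: StenosisGeometry) -> np.ndarray:
    """Volumetric flux Q at every axial station (shape (M+1,)).

    Computed as ``2 pi psi(wall)`` so the stream-function identity is exact.
    """
    return 2.0 * np.pi * stream_function(state, grid, geom)[:, -1]


def wall_shear_stress(
    state: FlowState, grid: Grid, geom: StenosisGeometry, mu: float = 1.0
) -> np.ndarray:
    """Wall shear stress tau at every axial station (shape (M+1,)).

    Uses the scheme's one-sided wall difference; ``mu`` is the viscosity in
    code units (default 1; see PhysicalScales for conversion to dyn/cm^2).
    """
    _check_compat(grid, geom)
    h = geom.wall_radius(grid.z)
    return -(mu / h) * (state.u[:, -1] - state.u[:, -2]) / grid.dx


def profile(
    state: FlowState,
    grid: Grid,
    geom: StenosisGeometry | None = None,
    z: float | None = None,
    x: float | None = None,
    physical_radius: bool = False,
) -> dict[str, np.ndarray]:
    """Extract a 1-D velocity profile along the nearest grid line.

    Exactly one of ``z`` (radial profile at an axial station) or ``x``
    (axial profile at a radial station) must be given.  Returns a dict with
    the slice coordinate array and the ``u`` and ``v`` values on it; for a
    z-slice, ``physical_radius=True`` maps the transformed coordinate back
    to ``r = x h(z)`` (requires ``geom``).
    """
    if (z is None) == (x is None):
        raise ValueError("specify exactly one of z or x")
    if z is not None:
        if not 0.0 <= z <= grid.domain_length:
            raise ValueError(f"z = {z} outside the domain [0, {grid.domain_length}]")
        i = int(round(z / grid.dz))
        coord = grid.x.copy()
        if physical_radius:
            if geom is None:
                raise ValueError("physical_radius=True requires the geometry")
            coord = coord * float(geom.wall_radius(grid.z[i]))
        return {
            "coord": coord,
            "u": state.u[i].copy(),
            "v": state.v[i].copy(),
            "z": grid.z[i],
        }
    assert x is not None
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x = {x} outside [0, 1]")
    j = int(round(x / grid.dx))
    return {
        "coord": grid.z.copy(),
        "u": state.u[:, j].copy(),
        "v": state.v[:, j].copy(),
        "x": grid.x[j],
    }


@dataclass
class ObservableSeries:
    """Flux, wall shear stress and stream function for a snapshot series.

    ``Q`` and ``tau`` have shape (n_snapshots, M+1); ``psi`` has shape
    (n_snapshots, M+1, N+1) and vanishes on the axis.
    """

    times: np.ndarray
    z: np.ndarray
    Q: np.ndarray
    tau: np.ndarray
    psi: np.ndarray
    mu: float = 1.0


def compute_observables(
    snapshots: Sequence[FlowState],
    grid: Grid,
    geom: StenosisGeometry,
    mu: float = 1.0,
) -> ObservableSeries:
    """Evaluate Q, tau and psi for every snapshot of a run."""
    psi = np.stack([stream_function(s, grid, geom) for s in snapshots])
    Q = 2.0 * np.pi * psi[:, :, -1]
    tau = np.stack([wall_shear_stress(s, grid, geom, mu) for s in snapshots])
    times = np.array([s.t for s in snapshots])
    return ObservableSeries(times=times, z=grid.z, Q=Q, tau=tau, psi=psi, mu=mu)
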