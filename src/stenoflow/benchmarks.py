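"""Analytic straight-tube oracles: Poiseuille and Womersley flow.

In the solver's nondimensionalization the straight-tube (h = 1) axial
momentum equation is linear when the advective terms vanish (v = 0, u
z-invariant):

    du/dt = p0 + p1 cos(omega t) + (1/Re) (u_xx + u_x / x).

Its steady part is the Poiseuille parabola ``u = (p0 Re / 4)(1 - x^2)``;
the oscillatory part is the classical Womersley solution

    u_osc(x, t) = Re{ (p1 / (i omega)) [1 - J0(i^{3/2} alpha x)
                                          / J0(i^{3/2} alpha)] e^{i omega t} },

with the Womersley number ``alpha = sqrt(omega Re)`` — the viscous term
carries 1/Re, so the balance i*omega*U ~ U''/Re fixes the Bessel argument
scale at sqrt(omega Re).  These closed forms are the package's independent
validation oracles for the finite-difference solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import jv

from .solver import FlowState, Grid

__all__ = [
    "WomersleyParams",
    "poiseuille",
    "womersley",
    "womersley_state",
    "ErrorReport",
    "compare",
    "poiseuille_validation",
    "womersley_validation",
    "grid_convergence_study",
    "field_difference_on_shared_nodes",
]


@dataclass(frozen=True)
class WomersleyParams:
    """Forcing and fluid parameters of the oscillatory straight-tube flow."""

    re: float = 400.0
    p0: float = 0.1
    p1: float = 0.02
    omega: float = 0.8

    def __post_init__(self) -> None:
        if self.re <= 0:
            raise ValueError("Reynolds number must be positive")
        if self.omega < 0:
            raise ValueError("omega must be non-negative")

    @property
    def alpha(self) -> float:
        """Womersley number sqrt(omega Re) in the code's units."""
        return math.sqrt(self.omega * self.re)

    @property
    def period(self) -> float:
        return 2.0 * math.pi / self.omega if self.omega > 0 else math.inf


def poiseuille(p0: float, re: float, x) -> np.ndarray:
    """Steady Poiseuille profile ``(p0 Re / 4)(1 - x^2)`` on 0 <= x <= 1."""
    x_arr = np.asarray(x, dtype=float)
    return 0.25 * p0 * re * (1.0 - x_arr**2)


def womersley(params: WomersleyParams, x, t: float) -> np.ndarray:
    """Axial velocity of pulsatile straight-tube flow at time ``t``.

    Superposition of the steady Poiseuille part (from ``p0``) and the
    oscillatory Womersley part (from ``p1 cos(omega t)``), evaluated with
    the complex Bessel function J0.  ``omega = 0`` degenerates to steady
    forcing ``p0 + p1``.
    """
    x_arr = np.asarray(x, dtype=float)
    if params.p1 == 0.0:
        return poiseuille(params.p0, params.re, x_arr)
    if params.omega == 0.0:
        return poiseuille(params.p0 + params.p1, params.re, x_arr)
    beta = 1j**1.5 * params.alpha
    denom = jv(0, beta)
    if not np.isfinite(denom) or abs(denom) < np.finfo(float).tiny:
        raise ValueError(
            f"J0(i^(3/2) alpha) not representable at alpha = {params.alpha:g}"
        )
    amplitude = params.p1 / (1j * params.omega) * (1.0 - jv(0, beta * x_arr) / denom)
    osc = np.real(amplitude * np.exp(1j * params.omega * t))
    return poiseuille(params.p0, params.re, x_arr) + osc


def womersley_state(grid: Grid, params: WomersleyParams, t: float = 0.0) -> FlowState:
    """Analytic straight-tube state on a solver grid (v = 0, u z-invariant).

    Used to start periodic-regime validation runs on the analytic solution,
    bypassing the slow viscous start-up transient (time constant ~ Re / j01^2).
    """
    u_profile = womersley(params, grid.x, t)
    u = np.tile(u_profile, (grid.M + 1, 1))
    return FlowState(u, np.zeros_like(u), t=t, n=0)


@dataclass(frozen=True)
class ErrorReport:
    """Relative error norms of a numeric field against an oracle field."""

    linf_rel: float
    l2_rel: float
    tol: float | None = None

    @property
    def passed(self) -> bool | None:
        return None if self.tol is None else self.linf_rel <= self.tol


def compare(numeric, reference, tol: float | None = None) -> ErrorReport:
    """L-infinity and L2 errors of ``numeric`` relative to ``reference``.

    Both arguments are arrays on the same nodes (oracle evaluated on the
    solver grid).  Errors are normalized by the corresponding norms of the
    reference; a zero reference falls back to absolute errors.
    """
    num = np.asarray(numeric, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if num.shape != ref.shape:
        raise ValueError(f"shape mismatch: {num.shape} vs {ref.shape}")
    diff = num - ref
    ref_linf = np.abs(ref).max()
    ref_l2 = np.linalg.norm(ref)
    linf = float(np.abs(diff).max() / (ref_linf if ref_linf > 0 else 1.0))
    l2 = float(np.linalg.norm(diff) / (ref_l2 if ref_l2 > 0 else 1.0))
    return ErrorReport(linf_rel=linf, l2_rel=l2, tol=tol)


# ---------------------------------------------------------------------- #
# validation drivers (used by the test suite, the CLI and the
# acceptance script)
# ---------------------------------------------------------------------- #
def _straight_tube(n_radial: int, n_axial: int, dt: float, domain_length: float = 10.0):
    from .geometry import StenosisGeometry
    from .solver import Grid

    geom = StenosisGeometry(lambda_=0.0, domain_length=domain_length)
    grid = Grid(M=n_axial, N=n_radial, domain_length=domain_length, dt=dt)
    return geom, grid


def poiseuille_validation(
    re: float = 400.0,
    p0: float = 0.1,
    n_radial: int = 60,
    n_axial: int = 8,
    dt: float = 0.04,
    tol: float = 1e-6,
) -> dict:
    """Steady straight-tube run compared against the Poiseuille solution.

    A straight tube (lambda = 0) under steady forcing converges to
    ``u = (p0 Re / 4)(1 - x^2)`` with centerline value p0 Re / 4, flux
    pi p0 Re / 8 and wall shear stress p0 Re / 2.  A straight-tube run is
    exactly z-invariant, so a small axial node count suffices; the discrete
    steady state is a fixed point independent of dt, and the default
    dt = 0.04 sits inside the diffusive stability bound for N <= 60.
    Returns the measured values, relative errors and the converged state.
    """
    from .forcing import BodyAcceleration, PressureForcing
    from .observables import flow_rate, wall_shear_stress
    from .solver import SolverConfig, run_to_steady

    geom, grid = _straight_tube(n_radial, n_axial, dt)
    pressure = PressureForcing(p0=p0, p1=0.0, omega=0.0)
    body = BodyAcceleration(a0=0.0, omega=0.0)
    state, info = run_to_steady(geom, grid, pressure, body, SolverConfig(re=re), tol=tol)

    mid = grid.M // 2
    centerline = float(state.u[mid, 0])
    q = float(flow_rate(state, grid, geom)[mid])
    tau = float(wall_shear_stress(state, grid, geom)[mid])
    exp_center = 0.25 * p0 * re
    exp_q = math.pi * p0 * re / 8.0
    exp_tau = 0.5 * p0 * re
    profile_err = compare(state.u[mid], poiseuille(p0, re, grid.x))
    return {
        "state": state,
        "grid": grid,
        "geom": geom,
        "n_steps": info["n_steps"],
        "centerline": centerline,
        "centerline_expected": exp_center,
        "centerline_rel_err": abs(centerline - exp_center) / exp_center,
        "flux": q,
        "flux_expected": exp_q,
        "flux_rel_err": abs(q - exp_q) / exp_q,
        "wall_shear": tau,
        "wall_shear_expected": exp_tau,
        "wall_shear_rel_err": abs(tau - exp_tau) / exp_tau,
        "profile_linf_rel": profile_err.linf_rel,
    }


def womersley_validation(
    params: WomersleyParams | None = None,
    n_radial: int = 100,
    n_axial: int = 10,
    dt: float = 0.001,
    periods: float = 5.0,
    phases_per_period: int = 8,
) -> dict:
    """Periodic-regime straight-tube run against the Womersley oracle.

    The run starts *on* the analytic solution at t = 0 (the viscous
    start-up transient of pipe flow decays with time constant ~ Re / j01^2,
    far longer than a few pulse periods) and is advanced for ``periods``
    forcing periods; snapshots spanning the final period are compared
    against the oracle evaluated at the same times.  Returns the largest
    relative L-infinity and L2 errors over those phases.
    """
    from .forcing import BodyAcceleration, PressureForcing
    from .solver import SolverConfig, simulate

    params = params if params is not None else WomersleyParams()
    geom, grid = _straight_tube(n_radial, n_axial, dt)
    pressure = PressureForcing(p0=params.p0, p1=params.p1, omega=params.omega)
    body = BodyAcceleration(a0=0.0, omega=params.omega)
    t_end = periods * params.period
    result = simulate(
        geom,
        grid,
        pressure,
        body,
        SolverConfig(re=params.re),
        t_end=t_end,
        snapshot_interval=params.period / phases_per_period,
        initial_state=womersley_state(grid, params),
    )
    t_lo = t_end - params.period - grid.dt
    linf = l2 = 0.0
    n_phases = 0
    for snap in result.snapshots:
        if snap.t < t_lo:
            continue
        oracle = womersley(params, grid.x, snap.t)
        report = compare(snap.u[grid.M // 2], oracle)
        linf = max(linf, report.linf_rel)
        l2 = max(l2, report.l2_rel)
        n_phases += 1
    return {
        "linf_rel": linf,
        "l2_rel": l2,
        "n_phases": n_phases,
        "alpha": params.alpha,
        "t_end": t_end,
        "result": result,
    }


def grid_convergence_study(
    n_coarse: int = 60,
    n_fine: int = 120,
    re: float = 400.0,
    p0: float = 0.1,
) -> dict:
    """Richardson-style refinement of the steady straight-tube error.

    Runs the steady Poiseuille recovery at two radial resolutions and
    reports the ratio of L-infinity profile errors; a nominally
    second-order scheme gives a ratio near (n_fine / n_coarse)^2.
    The finer grid uses a smaller dt to stay inside the diffusive bound.
    """
    out = {}
    for key, n in (("coarse", n_coarse), ("fine", n_fine)):
        dt = 0.04 if n <= 60 else 0.01
        res = poiseuille_validation(re=re, p0=p0, n_radial=n, dt=dt, tol=1e-7)
        out[key] = res
    ratio = out["coarse"]["profile_linf_rel"] / out["fine"]["profile_linf_rel"]
    return {
        "error_coarse": out["coarse"]["profile_linf_rel"],
        "error_fine": out["fine"]["profile_linf_rel"],
        "ratio": ratio,
        "n_coarse": n_coarse,
        "n_fine": n_fine,
    }


def field_difference_on_shared_nodes(u_a, grid_a, u_b, grid_b) -> float:
    """Relative L-infinity difference of two fields on their common lattice.

    The 60x60 and 100x100 default grids share the nodes with z a multiple of
    0.5 and x a multiple of 0.05; comparing there avoids polluting the metric
    with interpolation error across the near-wall layer.  Returns
    ``max |u_a - u_b| / max |u_b|`` over the shared nodes.
    """
    u_a = np.asarray(u_a)
    u_b = np.asarray(u_b)
    tol = 1e-9

    def shared(coords_a, coords_b):
        ia, ib = [], []
        j = 0
        for i, za in enumerate(coords_a):
            while j < len(coords_b) and coords_b[j] < za - tol:
                j += 1
            if j < len(coords_b) and abs(coords_b[j] - za) <= tol:
                ia.append(i)
                ib.append(j)
        return np.asarray(ia, dtype=int), np.asarray(ib, dtype=int)

    iz_a, iz_b = shared(grid_a.z, grid_b.z)
    ix_a, ix_b = shared(grid_a.x, grid_b.x)
    if iz_a.size < 3 or ix_a.size < 3:
        raise ValueError("grids share too few nodes for a meaningful comparison")
    sub_a = u_a[np.ix_(iz_a, ix_a)]
    sub_b = u_b[np.ix_(iz_b, ix_b)]
    scale = np.abs(sub_b).max()
    return float(np.abs(sub_a - sub_b).max() / (scale if scale > 0 else 1.0))
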