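"""Explicit finite-difference time stepper for the transformed flow equations.

The axisymmetric incompressible Navier-Stokes equations in the constricted
tube are mapped onto a fixed rectangle by the radial transformation
``x = r / h(z)`` (x in [0, 1], z in [0, L]).  In transformed variables the
continuity equation reads

    du/dz + v/(x h) + (1/h) dv/dx - (x/h) h' du/dx = 0,

and the axial momentum equation

    du/dt = -[ (v/h) du/dx + u du/dz - (x u / h) h' du/dx ] - dp/dz
            + (1/Re) [ (u_xx + u_x / x) / h^2 + u_zz ]
            - (1/Re) [ (2x/h) h' u_xz + (x/h) h'' u_x
                       - (h'/h)^2 (2x u_x + x^2 u_xx) ]
            + F_ext,

with the analogous radial momentum equation carrying an extra ``-v/x^2``
viscous term and no pressure/body-force contribution (the radial pressure
gradient is negligible for a long slender tube).

Discretization is forward in time on the node-centred lattice z_i = i dz,
x_j = j dx.  All viscous, metric and mixed derivatives use the classical
central stencils; the advective derivatives are upwinded by default
(second-order linear upwind along z, donor-cell along x), because the
fully centred explicit scheme is linearly unstable for this flow once the
axial velocity exceeds the cell-Peclet limit sqrt(2/(Re dt)) — about 0.7
at the default dt = 0.01 — which the pressure-driven start-up crosses
before t = 10.  ``SolverConfig(advection="central")`` selects the fully
centred variant; the two coincide wherever the advective terms vanish
(straight tube, z-invariant or quiescent flow), which covers every
analytic benchmark regime.  Each step advances u from the axial momentum
equation and then *reconstructs* v by integrating the transformed
continuity equation outward from the axis with the trapezoidal rule,

    x v(x) = -h(z) * int_0^x x' [ du/dz - (x'/h) h' du/dx ] dx',

which enforces discrete mass conservation to rounding error at every
interior cell.  The radial momentum equation is kept as a residual
diagnostic (:func:`radial_momentum_residual`), not used to advance v.

Boundary conditions, re-imposed after every step:

* wall (x = 1):  u = v = 0 (no slip on the rigid wall);
* axis (x = 0):  v = 0 and the discrete symmetry u[:, 0] = u[:, 1]
  (the singular 1/x terms are never evaluated on the axis row);
* inlet/outlet (z = 0, L): zero axial gradient (copied nodes), modelling
  fully developed flow far from the stenoses.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .forcing import BodyAcceleration, PressureForcing
from .geometry import StenosisGeometry

__all__ = [
    "Grid",
    "FlowState",
    "SolverConfig",
    "RunResult",
    "BlowUpError",
    "StabilityWarning",
    "initialize",
    "stability_bound",
    "step",
    "simulate",
    "run_to_steady",
    "continuity_residual",
    "radial_momentum_residual",
]

logger = logging.getLogger("stenoflow")


class BlowUpError(RuntimeError):
    """Raised when the explicit scheme diverges (non-finite or huge fields)."""


class StabilityWarning(UserWarning):
    """Issued when the time step exceeds the estimated explicit stability bound."""


# ---------------------------------------------------------------------- #
# grid and state containers
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class Grid:
    """Rectangular computational lattice for the transformed domain.

    ``M`` axial intervals on [0, L] and ``N`` radial intervals on [0, 1];
    nodes are z_i = i dz (i = 0..M) and x_j = j dx (j = 0..N).
    """

    M: int = 60
    N: int = 60
    domain_length: float = 10.0
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.M < 4 or self.N < 4:
            raise ValueError("grid must have at least 4 intervals per direction")
        if self.dt <= 0:
            raise ValueError("time step dt must be positive")
        if self.domain_length <= 0:
            raise ValueError("domain_length must be positive")

    @property
    def dz(self) -> float:
        return self.domain_length / self.M

    @property
    def dx(self) -> float:
        return 1.0 / self.N

    @property
    def z(self) -> np.ndarray:
        return np.linspace(0.0, self.domain_length, self.M + 1)

    @property
    def x(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.N + 1)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.M + 1, self.N + 1)


@dataclass
class FlowState:
    """Velocity fields at one time level.

    ``u`` (axial) and ``v`` (radial) have shape ``(M+1, N+1)``; first index
    axial, second radial.  ``t`` is the current time and ``n`` the step
    counter.
    """

    u: np.ndarray
    v: np.ndarray
    t: float = 0.0
    n: int = 0

    def copy(self) -> "FlowState":
        return FlowState(self.u.copy(), self.v.copy(), self.t, self.n)

    @property
    def max_speed(self) -> float:
        return float(max(np.abs(self.u).max(), np.abs(self.v).max()))


#: default half-width (tube-radius units) of the C1 rounding applied to the
#: wall-slope corners at the stenosis junctions in the solver metric tables
DEFAULT_JUNCTION_ROUNDING = 0.4


@dataclass(frozen=True)
class SolverConfig:
    """Numerical parameters of the explicit scheme.

    ``advection`` selects the discretization of the advective derivatives:
    ``"upwind"`` (default; second-order upwind in z, donor-cell in x) or
    ``"central"`` (fully centred stencils — stable only while the flow
    stays below the cell-Peclet limit).  ``junction_rounding`` is the
    half-width over which the metric tables blend the wall-slope corners at
    the stenosis junctions (the printed cosine profile is only C0 there);
    0 uses the raw one-sided derivatives.
    """

    re: float = 400.0
    safety_factor: float = 0.9
    max_steps: int = 10_000_000
    divergence_threshold: float = 1e6
    advection: str = "upwind"
    junction_rounding: float = DEFAULT_JUNCTION_ROUNDING

    def __post_init__(self) -> None:
        if self.re <= 0:
            raise ValueError("Reynolds number must be positive")
        if not 0 < self.safety_factor <= 1:
            raise ValueError("safety_factor must lie in (0, 1]")
        if self.advection not in ("upwind", "central"):
            raise ValueError("advection must be 'upwind' or 'central'")
        if self.junction_rounding < 0:
            raise ValueError("junction_rounding must be non-negative")


@dataclass
class _WallTables:
    """Geometry arrays sampled on the axial nodes (cached per run)."""

    h: np.ndarray
    dh: np.ndarray
    d2h: np.ndarray


def _tables(
    grid: Grid,
    geom: StenosisGeometry,
    junction_rounding: float = DEFAULT_JUNCTION_ROUNDING,
) -> _WallTables:
    """Geometry tables; corners of dh/dz rounded over a fixed physical width.

    The printed wall profile is continuous but its slope jumps at the three
    stenosis junctions; the solver blends (h, dh, d2h) across each junction
    with a C1 cubic Hermite over ``[zj - w, zj + w]`` so both coarse and
    fine grids discretize the same regular geometry.  The public geometry
    methods are untouched.
    """
    z = grid.z
    h = geom.wall_radius(z)
    dh = geom.wall_slope(z)
    d2h = geom.wall_curvature(z)
    w = junction_rounding
    if geom.lambda_ == 0.0 or w <= 0.0:
        return _WallTables(h, dh, d2h)
    for zj in (geom.d, geom.d + geom.l, geom.d + 2.0 * geom.l):
        a, b = zj - w, zj + w
        if a < 0.0 or b > geom.domain_length:
            continue
        ha, hb = geom.wall_radius(a), geom.wall_radius(b)
        da, db = geom.wall_slope(a), geom.wall_slope(b)
        m = (z > a) & (z < b)
        if not np.any(m):
            continue
        span = 2.0 * w
        s = (z[m] - a) / span
        h[m] = (
            (2 * s**3 - 3 * s**2 + 1) * ha
            + (s**3 - 2 * s**2 + s) * span * da
            + (-2 * s**3 + 3 * s**2) * hb
            + (s**3 - s**2) * span * db
        )
        dh[m] = (
            (6 * s**2 - 6 * s) * ha
            + (3 * s**2 - 4 * s + 1) * span * da
            + (-6 * s**2 + 6 * s) * hb
            + (3 * s**2 - 2 * s) * span * db
        ) / span
        d2h[m] = (
            (12 * s - 6) * ha
            + (6 * s - 4) * span * da
            + (-12 * s + 6) * hb
            + (6 * s - 2) * span * db
        ) / span**2
    return _WallTables(h, dh, d2h)


def _check_compat(grid: Grid, geom: StenosisGeometry) -> None:
    if abs(grid.domain_length - geom.domain_length) > 1e-12:
        raise ValueError(
            "grid and geometry disagree on the domain length: "
            f"{grid.domain_length} vs {geom.domain_length}"
        )


# ---------------------------------------------------------------------- #
# initialization and stability
# ---------------------------------------------------------------------- #
def initialize(grid: Grid, geom: StenosisGeometry) -> FlowState:
    """Quiescent initial state: u = v = 0 everywhere at t = 0."""
    _check_compat(grid, geom)
    shape = grid.shape
    return FlowState(np.zeros(shape), np.zeros(shape), t=0.0, n=0)


def stability_bound(
    grid: Grid,
    geom: StenosisGeometry,
    config: SolverConfig,
    state: FlowState | None = None,
) -> float:
    """Conservative admissible time step for the explicit scheme.

    Combines the diffusive FTCS bound ``(Re/2) / ((h dx)^-2 + dz^-2)``
    (minimized over the wall profile, i.e. evaluated at the throat) with
    advective Courant bounds based on the current velocity field, scaled by
    ``config.safety_factor``.  With a quiescent (or absent) state only the
    diffusive part constrains the step.
    """
    _check_compat(grid, geom)
    h_min = float(np.min(geom.wall_radius(grid.z)))
    diffusive = 0.5 * config.re / ((h_min * grid.dx) ** -2 + grid.dz**-2)
    bound = diffusive
    if state is not None:
        u_max = float(np.abs(state.u).max())
        v_max = float(np.abs(state.v).max())
        if u_max > 0:
            bound = min(bound, grid.dz / u_max)
        if v_max > 0:
            bound = min(bound, h_min * grid.dx / v_max)
    return config.safety_factor * bound


# ---------------------------------------------------------------------- #
# discrete operators
# ---------------------------------------------------------------------- #
def _axial_rhs(
    u: np.ndarray,
    v: np.ndarray,
    grid: Grid,
    tab: _WallTables,
    re: float,
    pressure_gradient: float,
    body_force: float,
    advection: str = "upwind",
) -> np.ndarray:
    """du/dt at the interior nodes (shape (M-1, N-1)).

    Viscous, metric and mixed derivatives are centred.  The advective group
    is written with the combined transformed velocities c_x = (v - x u h')/h
    and c_z = u; with ``advection="upwind"`` c_x u_x uses donor-cell and
    c_z u_z second-order upwind differences (first-order fallback on the
    rows adjacent to the inlet/outlet), with ``"central"`` both are centred.
    """
    dx, dz = grid.dx, grid.dz
    x = grid.x[None, 1:-1]
    h = tab.h[1:-1, None]
    dh = tab.dh[1:-1, None]
    d2h = tab.d2h[1:-1, None]

    uc = u[1:-1, 1:-1]
    vc = v[1:-1, 1:-1]
    u_x = (u[1:-1, 2:] - u[1:-1, :-2]) / (2.0 * dx)
    u_xx = (u[1:-1, 2:] - 2.0 * uc + u[1:-1, :-2]) / dx**2
    u_zz = (u[2:, 1:-1] - 2.0 * uc + u[:-2, 1:-1]) / dz**2
    u_xz = (u[2:, 2:] - u[2:, :-2] - u[:-2, 2:] + u[:-2, :-2]) / (4.0 * dx * dz)

    c_x = (vc - x * uc * dh) / h
    if advection == "central":
        u_z = (u[2:, 1:-1] - u[:-2, 1:-1]) / (2.0 * dz)
        adv = c_x * u_x + uc * u_z
    else:
        uz_back = np.empty_like(uc)
        uz_back[0] = (uc[0] - u[0, 1:-1]) / dz
        uz_back[1:] = (3.0 * u[2:-1, 1:-1] - 4.0 * u[1:-2, 1:-1] + u[:-3, 1:-1]) / (
            2.0 * dz
        )
        uz_fwd = np.empty_like(uc)
        uz_fwd[-1] = (u[-1, 1:-1] - uc[-1]) / dz
        uz_fwd[:-1] = (-3.0 * u[1:-2, 1:-1] + 4.0 * u[2:-1, 1:-1] - u[3:, 1:-1]) / (
            2.0 * dz
        )
        ux_back = (uc - u[1:-1, :-2]) / dx
        ux_fwd = (u[1:-1, 2:] - uc) / dx
        adv = np.where(c_x > 0.0, c_x * ux_back, c_x * ux_fwd) + np.where(
            uc > 0.0, uc * uz_back, uc * uz_fwd
        )

    viscous = ((u_xx + u_x / x) / h**2 + u_zz) / re
    metric = (
        2.0 * x / h * dh * u_xz
        + x / h * d2h * u_x
        - (dh / h) ** 2 * (2.0 * x * u_x + x**2 * u_xx)
    ) / re
    return -adv + pressure_gradient + viscous - metric + body_force


def _radial_rhs(
    u: np.ndarray,
    v: np.ndarray,
    grid: Grid,
    tab: _WallTables,
    re: float,
) -> np.ndarray:
    """dv/dt at the interior nodes from the transformed radial momentum equation."""
    dx, dz = grid.dx, grid.dz
    x = grid.x[None, 1:-1]
    h = tab.h[1:-1, None]
    dh = tab.dh[1:-1, None]
    d2h = tab.d2h[1:-1, None]

    uc = u[1:-1, 1:-1]
    vc = v[1:-1, 1:-1]
    v_x = (v[1:-1, 2:] - v[1:-1, :-2]) / (2.0 * dx)
    v_xx = (v[1:-1, 2:] - 2.0 * vc + v[1:-1, :-2]) / dx**2
    v_z = (v[2:, 1:-1] - v[:-2, 1:-1]) / (2.0 * dz)
    v_zz = (v[2:, 1:-1] - 2.0 * vc + v[:-2, 1:-1]) / dz**2
    v_xz = (v[2:, 2:] - v[2:, :-2] - v[:-2, 2:] + v[:-2, :-2]) / (4.0 * dx * dz)

    advection = vc / h * v_x + uc * v_z - x * uc / h * dh * v_x
    viscous = ((v_xx + v_x / x - vc / x**2) / h**2 + v_zz) / re
    metric = (
        2.0 * x / h * dh * v_xz
        + x / h * d2h * v_x
        - (dh / h) ** 2 * (2.0 * x * v_x + x**2 * v_xx)
    ) / re
    return -advection + viscous - metric


def _continuity_integrand(u: np.ndarray, grid: Grid, tab: _WallTables) -> np.ndarray:
    """g(x, z) = x [du/dz - (x/h) h' du/dx], the source integrated to obtain v."""
    dx, dz = grid.dx, grid.dz
    u_z = np.zeros_like(u)
    u_z[1:-1] = (u[2:] - u[:-2]) / (2.0 * dz)
    # zero axial gradient at the copied inlet/outlet rows -> u_z = 0 there
    u_x = np.zeros_like(u)
    u_x[:, 1:-1] = (u[:, 2:] - u[:, :-2]) / (2.0 * dx)
    u_x[:, -1] = (u[:, -1] - u[:, -2]) / dx
    # u_x on the axis column is irrelevant: the integrand carries a factor x = 0
    x = grid.x[None, :]
    return x * (u_z - x / tab.h[:, None] * tab.dh[:, None] * u_x)


def _reconstruct_v(u: np.ndarray, grid: Grid, tab: _WallTables) -> np.ndarray:
    """Radial velocity from the transformed continuity equation.

    Outward trapezoidal integration from the axis:
    ``x v = -h * cumtrapz(g, dx)`` with g from :func:`_continuity_integrand`.
    """
    g = _continuity_integrand(u, grid, tab)
    xv = -tab.h[:, None] * cumulative_trapezoid(g, dx=grid.dx, initial=0.0, axis=1)
    v = np.zeros_like(u)
    v[:, 1:] = xv[:, 1:] / grid.x[None, 1:]
    return v


# ---------------------------------------------------------------------- #
# time stepping
# ---------------------------------------------------------------------- #
def step(
    state: FlowState,
    grid: Grid,
    geom: StenosisGeometry,
    pressure: PressureForcing,
    body: BodyAcceleration,
    config: SolverConfig,
    _tab: _WallTables | None = None,
    check_stability: bool = False,
) -> FlowState:
    """Advance the flow by one forward-Euler step of size ``grid.dt``.

    The axial momentum equation updates u at the interior nodes; boundary
    conditions are re-imposed; v is then reconstructed from the transformed
    continuity equation at the new level and its wall/axis conditions
    applied.  Raises :class:`BlowUpError` if the fields become non-finite or
    exceed ``config.divergence_threshold``.
    """
    tab = _tab if _tab is not None else _tables(grid, geom, config.junction_rounding)
    if _tab is None:
        _check_compat(grid, geom)
    if check_stability:
        bound = stability_bound(grid, geom, config, state)
        if grid.dt > bound:
            warnings.warn(
                f"dt = {grid.dt:g} exceeds the estimated stability bound "
                f"{bound:g} at t = {state.t:g}",
                StabilityWarning,
                stacklevel=2,
            )

    pg = float(pressure.pressure_gradient(state.t))
    fext = float(body.body_force(state.t))

    u_new = state.u.copy()
    u_new[1:-1, 1:-1] += grid.dt * _axial_rhs(
        state.u, state.v, grid, tab, config.re, pg, fext, advection=config.advection
    )
    # boundary conditions: wall no-slip, axis symmetry, zero-gradient ends
    u_new[:, -1] = 0.0
    u_new[:, 0] = u_new[:, 1]
    u_new[0, :] = u_new[1, :]
    u_new[-1, :] = u_new[-2, :]

    v_new = _reconstruct_v(u_new, grid, tab)
    v_new[:, 0] = 0.0
    v_new[:, -1] = 0.0

    n_new = state.n + 1
    u_ceil = np.abs(u_new).max()
    if not math.isfinite(u_ceil) or u_ceil > config.divergence_threshold:
        raise BlowUpError(
            f"solution blew up at step {n_new} (t = {n_new * grid.dt:g}): "
            f"max |u| = {u_ceil:g}"
        )
    return FlowState(u_new, v_new, t=n_new * grid.dt, n=n_new)


@dataclass
class RunResult:
    """Time series of snapshots produced by :func:`simulate`."""

    snapshots: list[FlowState]
    grid: Grid
    geom: StenosisGeometry
    pressure: PressureForcing
    body: BodyAcceleration
    config: SolverConfig
    manifest: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t for s in self.snapshots])

    @property
    def final(self) -> FlowState:
        return self.snapshots[-1]


def simulate(
    geom: StenosisGeometry,
    grid: Grid,
    pressure: PressureForcing,
    body: BodyAcceleration,
    config: SolverConfig,
    t_end: float,
    snapshot_interval: float | None = None,
    initial_state: FlowState | None = None,
    log_every: int = 100,
) -> RunResult:
    """Run the solver from ``initial_state`` (default: rest) to ``t_end``.

    Snapshots are recorded at the requested cadence — a snapshot time ``ts``
    is taken at the first step with ``t >= ts - dt/2`` — plus the initial
    and final states.  The scheme is fully deterministic: identical inputs
    give bit-identical outputs.
    """
    _check_compat(grid, geom)
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    tab = _tables(grid, geom, config.junction_rounding)
    state = initial_state if initial_state is not None else initialize(grid, geom)
    if state.u.shape != grid.shape:
        raise ValueError("initial state does not match the grid shape")

    snapshots = [state.copy()]
    interval = snapshot_interval if snapshot_interval is not None else math.inf
    next_snap = state.t + interval
    n_steps = int(round((t_end - state.t) / grid.dt))
    if n_steps > config.max_steps:
        raise ValueError(f"run would take {n_steps} steps > max_steps={config.max_steps}")

    warned = False
    for k in range(n_steps):
        if k % log_every == 0:
            bound = stability_bound(grid, geom, config, state)
            logger.debug(
                "step %d t=%.4f max|u|=%.4g dt_max=%.4g", state.n, state.t,
                state.max_speed, bound,
            )
            if grid.dt > bound and not warned:
                warnings.warn(
                    f"dt = {grid.dt:g} exceeds the estimated stability bound "
                    f"{bound:g} at t = {state.t:g}",
                    StabilityWarning,
                    stacklevel=2,
                )
                warned = True
        state = step(state, grid, geom, pressure, body, config, _tab=tab)
        if state.t >= next_snap - grid.dt / 2:
            snapshots.append(state.copy())
            next_snap += interval
    if snapshots[-1].n != state.n:
        snapshots.append(state.copy())
    return RunResult(snapshots, grid, geom, pressure, body, config)


def run_to_steady(
    geom: StenosisGeometry,
    grid: Grid,
    pressure: PressureForcing,
    body: BodyAcceleration,
    config: SolverConfig,
    tol: float = 1e-6,
    check_every: int = 50,
    max_time: float = 5000.0,
) -> tuple[FlowState, dict]:
    """Advance until the field is stationary: ``max|du/dt| <= tol``.

    Intended for steady forcing (p1 = a0 = 0); returns the converged state
    and an info dict with the step count and final residual.  Raises
    :class:`BlowUpError` on divergence and ``RuntimeError`` if ``max_time``
    is reached without convergence.
    """
    _check_compat(grid, geom)
    tab = _tables(grid, geom, config.junction_rounding)
    state = initialize(grid, geom)
    residual = math.inf
    while state.t < max_time:
        prev = state.u
        for _ in range(check_every):
            state = step(state, grid, geom, pressure, body, config, _tab=tab)
        residual = float(np.abs(state.u - prev).max()) / (check_every * grid.dt)
        if residual <= tol:
            return state, {"n_steps": state.n, "residual": residual, "t": state.t}
    raise RuntimeError(
        f"no steady state within t = {max_time}: residual {residual:g} > tol {tol:g}"
    )


# ---------------------------------------------------------------------- #
# diagnostics
# ---------------------------------------------------------------------- #
def continuity_residual(
    state: FlowState,
    grid: Grid,
    geom: StenosisGeometry,
    config: SolverConfig | None = None,
) -> np.ndarray:
    """Trapezoidal-cell residual of the transformed continuity equation.

    For each axial station and each radial cell [x_j, x_{j+1}] away from the
    wall the reconstruction guarantees

        (x_{j+1} v_{j+1} - x_j v_j) / dx + h (g_j + g_{j+1}) / 2 = 0

    to rounding error; the returned array (shape ``(M+1, N-1)``) covers the
    interior cells j = 0..N-2.  The wall cell is excluded because the no-slip
    condition overrides the reconstructed v there.  ``config`` supplies the
    junction-rounding width the run was made with (defaults match
    :class:`SolverConfig`).
    """
    _check_compat(grid, geom)
    rounding = config.junction_rounding if config is not None else DEFAULT_JUNCTION_ROUNDING
    tab = _tables(grid, geom, rounding)
    g = _continuity_integrand(state.u, grid, tab)
    xv = grid.x[None, :] * state.v
    flux_div = (xv[:, 1:] - xv[:, :-1]) / grid.dx
    source = tab.h[:, None] * 0.5 * (g[:, :-1] + g[:, 1:])
    return (flux_div + source)[:, :-1]


def radial_momentum_residual(
    prev: FlowState,
    new: FlowState,
    grid: Grid,
    geom: StenosisGeometry,
    config: SolverConfig,
) -> np.ndarray:
    """FTCS residual of the (unused) radial momentum equation.

    Evaluates ``(v_new - v_prev)/dt - RHS(prev)`` at the interior nodes,
    where RHS is the transformed radial momentum operator (radial pressure
    gradient neglected, no body-force component).  Because v is obtained
    from continuity rather than from this equation, the residual measures
    how closely the reconstruction honours radial momentum; it vanishes for
    quiescent flow and shrinks with the truncation error for smooth flows.
    """
    _check_compat(grid, geom)
    if new.n - prev.n != 1:
        raise ValueError("radial_momentum_residual expects two consecutive states")
    tab = _tables(grid, geom, config.junction_rounding)
    dvdt = (new.v[1:-1, 1:-1] - prev.v[1:-1, 1:-1]) / grid.dt
    return dvdt - _radial_rhs(prev.u, prev.v, grid, tab, config.re)
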