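import math

import numpy as np
import pytest

from stenoflow import (
    BlowUpError,
    BodyAcceleration,
    FlowState,
    Grid,
    PressureForcing,
    SolverConfig,
    StabilityWarning,
    StenosisGeometry,
    continuity_residual,
    initialize,
    radial_momentum_residual,
    run_to_steady,
    simulate,
    stability_bound,
    step,
)
from stenoflow.solver import _axial_rhs, _radial_rhs, _reconstruct_v, _tables

from conftest import assert_boundary_conditions


class TestGridAndConfig:
    def test_grid_spacings(self):
        g = Grid(M=60, N=60, domain_length=10.0, dt=0.01)
        assert g.dz == pytest.approx(1 / 6)
        assert g.dx == pytest.approx(1 / 60)
        assert g.z[0] == 0.0 and g.z[-1] == 10.0
        assert g.x[0] == 0.0 and g.x[-1] == 1.0

    @pytest.mark.parametrize(
        "kwargs", [dict(M=3), dict(N=2), dict(dt=0.0), dict(domain_length=-1.0)]
    )
    def test_invalid_grid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Grid(**{**dict(M=20, N=20, dt=0.01), **kwargs})

    def test_invalid_solver_config_rejected(self):
        with pytest.raises(ValueError):
            SolverConfig(re=-1.0)
        with pytest.raises(ValueError):
            SolverConfig(safety_factor=1.5)
        with pytest.raises(ValueError):
            SolverConfig(advection="qutck")


class TestInitializeAndStabilityBound:
    def test_initial_state_is_quiescent(self, default_geometry):
        grid = Grid()
        state = initialize(grid, default_geometry)
        assert state.t == 0.0 and state.n == 0
        assert np.all(state.u == 0.0) and np.all(state.v == 0.0)

    def test_domain_mismatch_rejected(self, default_geometry):
        with pytest.raises(ValueError, match="domain length"):
            initialize(Grid(domain_length=8.0), StenosisGeometry(domain_length=10.0))

    def test_diffusive_bound_closed_form(self, straight_geometry):
        """Straight tube, unit safety: bound = (Re/2) / (N^2 + (M/L)^2)."""
        grid = Grid(M=60, N=60, domain_length=10.0, dt=0.01)
        cfg = SolverConfig(re=400.0, safety_factor=1.0)
        bound = stability_bound(grid, straight_geometry, cfg)
        assert bound == pytest.approx(200.0 / 3636.0, rel=1e-12)

    def test_halving_dx_quarters_diffusive_bound(self, straight_geometry):
        cfg = SolverConfig(re=400.0, safety_factor=1.0)
        b60 = stability_bound(Grid(M=8, N=60, dt=0.01), straight_geometry, cfg)
        b120 = stability_bound(Grid(M=8, N=120, dt=0.01), straight_geometry, cfg)
        # axial term is negligible at M=8, so the ratio is essentially 4
        assert b60 / b120 == pytest.approx(4.0, rel=0.01)

    def test_bound_linear_in_reynolds(self, straight_geometry):
        grid = Grid(M=60, N=60, dt=0.01)
        b400 = stability_bound(grid, straight_geometry, SolverConfig(re=400.0))
        b800 = stability_bound(grid, straight_geometry, SolverConfig(re=800.0))
        assert b800 == pytest.approx(2.0 * b400)

    def test_advective_part_uses_current_velocities(self, straight_geometry):
        grid = Grid(M=60, N=60, dt=0.01)
        cfg = SolverConfig(re=400.0, safety_factor=1.0)
        state = initialize(grid, straight_geometry)
        state.u += 10.0  # fast flow: dz / |u| binds
        bound = stability_bound(grid, straight_geometry, cfg, state)
        assert bound == pytest.approx(grid.dz / 10.0)


class TestStep:
    def test_uniform_impulse_from_rest(self, straight_geometry):
        """One step from rest under steady forcing raises interior u by dt p0."""
        grid = Grid(M=20, N=20, dt=0.01)
        pr = PressureForcing(p0=0.1, p1=0.0, omega=0.0)
        bo = BodyAcceleration(a0=0.0, omega=0.0)
        new = step(initialize(grid, straight_geometry), grid, straight_geometry, pr, bo, SolverConfig())
        assert np.allclose(new.u[5, :-1], grid.dt * 0.1)
        assert np.all(new.u[:, -1] == 0.0)
        assert np.all(new.v == 0.0)
        assert new.t == pytest.approx(grid.dt) and new.n == 1

    def test_zero_forcing_is_fixed_point(self, default_geometry):
        grid = Grid(M=20, N=20, dt=0.005)
        pr = PressureForcing(p0=0.0, p1=0.0, omega=0.0)
        bo = BodyAcceleration(a0=0.0, omega=0.0)
        state = initialize(grid, default_geometry)
        for _ in range(20):
            state = step(state, grid, default_geometry, pr, bo, SolverConfig())
        assert np.all(state.u == 0.0) and np.all(state.v == 0.0)

    def test_boundary_conditions_after_every_step(self, default_geometry):
        grid = Grid(M=30, N=30, dt=0.005)
        pr = PressureForcing()
        bo = BodyAcceleration()
        cfg = SolverConfig()
        state = initialize(grid, default_geometry)
        for _ in range(50):
            state = step(state, grid, default_geometry, pr, bo, cfg)
            assert_boundary_conditions(state)

    def test_mass_conservation_by_construction(self, default_geometry):
        grid = Grid(M=30, N=30, dt=0.005)
        cfg = SolverConfig()
        state = initialize(grid, default_geometry)
        for _ in range(60):
            state = step(state, grid, default_geometry, PressureForcing(), BodyAcceleration(), cfg)
        res = continuity_residual(state, grid, default_geometry, cfg)
        assert np.abs(res).max() < 1e-10

    def test_blowup_raises(self, default_geometry):
        grid = Grid(M=30, N=30, dt=2.0)  # far beyond any stability bound
        cfg = SolverConfig(advection="central")
        state = initialize(grid, default_geometry)
        with pytest.raises(BlowUpError, match="blew up"):
            for _ in range(200):
                state = step(state, grid, default_geometry, PressureForcing(), BodyAcceleration(), cfg)

    def test_stability_warning_when_dt_too_large(self, straight_geometry):
        grid = Grid(M=60, N=60, dt=0.06)  # above the 0.049 diffusive bound
        with pytest.warns(StabilityWarning):
            simulate(
                straight_geometry,
                grid,
                PressureForcing(p0=0.1, p1=0.0, omega=0.0),
                BodyAcceleration(a0=0.0, omega=0.0),
                SolverConfig(),
                t_end=0.3,
            )


class TestSimulate:
    def test_step_count_and_final_time(self, straight_geometry):
        grid = Grid(M=8, N=20, dt=0.01)
        result = simulate(
            straight_geometry,
            grid,
            PressureForcing(p0=0.1, p1=0.0, omega=0.0),
            BodyAcceleration(a0=0.0, omega=0.0),
            SolverConfig(),
            t_end=1.0,
            snapshot_interval=0.25,
        )
        assert result.final.n == 100
        assert result.final.t == pytest.approx(1.0)
        assert len(result.snapshots) == 5  # t = 0, .25, .5, .75, 1.0

    def test_sparse_cadence_keeps_first_and_last(self, straight_geometry):
        grid = Grid(M=8, N=20, dt=0.01)
        result = simulate(
            straight_geometry,
            grid,
            PressureForcing(p0=0.1, p1=0.0, omega=0.0),
            BodyAcceleration(a0=0.0, omega=0.0),
            SolverConfig(),
            t_end=0.5,
            snapshot_interval=10.0,
        )
        assert len(result.snapshots) == 2
        assert result.snapshots[0].t == 0.0
        assert result.snapshots[-1].t == pytest.approx(0.5)

    def test_determinism_bit_identical(self, default_geometry):
        grid = Grid(M=20, N=20, dt=0.005)
        args = (default_geometry, grid, PressureForcing(), BodyAcceleration(), SolverConfig())
        a = simulate(*args, t_end=0.2)
        b = simulate(*args, t_end=0.2)
        assert np.array_equal(a.final.u, b.final.u)
        assert np.array_equal(a.final.v, b.final.v)

    def test_run_to_steady_reaches_poiseuille(self, straight_geometry):
        grid = Grid(M=8, N=20, dt=0.05)
        state, info = run_to_steady(
            straight_geometry,
            grid,
            PressureForcing(p0=0.1, p1=0.0, omega=0.0),
            BodyAcceleration(a0=0.0, omega=0.0),
            SolverConfig(re=400.0),
            tol=1e-6,
        )
        assert info["residual"] <= 1e-6
        assert state.u[4, 0] == pytest.approx(10.0, rel=0.02)


class TestOperatorConsistency:
    """Pin the discrete operators to the physical-space equations via sympy."""

    @staticmethod
    def _fields_and_oracles():
        import sympy as sp

        r, zz, xs = sp.symbols("r z x", positive=True)
        lam, l, d = sp.Rational(3, 10), sp.Integer(2), sp.Integer(3)
        h = 1 - lam * sp.cos(sp.pi * zz / l)  # first cosine branch, z in [3, 5)
        # smooth transformed-coordinate test fields (no-slip not required here)
        uhat = (1 - xs**2) * (1 + sp.Rational(3, 10) * sp.sin(zz))
        vhat = sp.Rational(1, 5) * xs * (1 - xs**2) * sp.sin(2 * zz)
        u_phys = uhat.subs(xs, r / h)
        v_phys = vhat.subs(xs, r / h)
        Re = sp.Integer(400)
        rhs_u = -(v_phys * sp.diff(u_phys, r) + u_phys * sp.diff(u_phys, zz)) + (
            sp.diff(u_phys, r, 2) + sp.diff(u_phys, r) / r + sp.diff(u_phys, zz, 2)
        ) / Re
        rhs_v = -(v_phys * sp.diff(v_phys, r) + u_phys * sp.diff(v_phys, zz)) + (
            sp.diff(v_phys, r, 2)
            + sp.diff(v_phys, r) / r
            - v_phys / r**2
            + sp.diff(v_phys, zz, 2)
        ) / Re
        return (
            sp.lambdify((xs, zz), uhat, "numpy"),
            sp.lambdify((xs, zz), vhat, "numpy"),
            sp.lambdify((r, zz), rhs_u, "numpy"),
            sp.lambdify((r, zz), rhs_v, "numpy"),
            sp.lambdify(zz, h, "numpy"),
        )

    def test_transformed_operators_match_physical_equations(self):
        """Central discrete RHS converges (2nd order) to the (r, z) operators."""
        uh, vh, rhs_u_fn, rhs_v_fn, h_fn = self._fields_and_oracles()
        geom = StenosisGeometry(lambda_=0.3, l=2.0, d=3.0)
        probe_z, probe_x = 4.25, 0.5  # a shared node, inside the smooth branch
        errs_u, errs_v = [], []
        for mn in (40, 80, 160):
            grid = Grid(M=mn, N=mn, domain_length=10.0, dt=1e-3)
            X, Z = np.meshgrid(grid.x, grid.z)
            u = uh(X, Z)
            v = vh(X, Z)
            tab = _tables(grid, geom, junction_rounding=0.0)
            rhs_u = _axial_rhs(u, v, grid, tab, 400.0, 0.0, 0.0, advection="central")
            rhs_v = _radial_rhs(u, v, grid, tab, 400.0)
            iz = round(probe_z / grid.dz)
            ix = round(probe_x / grid.dx)
            r_probe = probe_x * h_fn(probe_z)
            errs_u.append(abs(rhs_u[iz - 1, ix - 1] - rhs_u_fn(r_probe, probe_z)))
            errs_v.append(abs(rhs_v[iz - 1, ix - 1] - rhs_v_fn(r_probe, probe_z)))
        for errs in (errs_u, errs_v):
            assert errs[-1] < 5e-4
            assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.3)
            assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.3)

    def test_upwind_advection_consistent_with_central(self):
        """Upwind and central RHS agree to O(dz^2 + dx) on smooth fields."""
        uh, vh, *_ = self._fields_and_oracles()
        geom = StenosisGeometry(lambda_=0.3, l=2.0, d=3.0)
        diffs = []
        for mn in (40, 80):
            grid = Grid(M=mn, N=mn, domain_length=10.0, dt=1e-3)
            X, Z = np.meshgrid(grid.x, grid.z)
            u = uh(X, Z)
            v = vh(X, Z)
            tab = _tables(grid, geom, junction_rounding=0.0)
            a = _axial_rhs(u, v, grid, tab, 400.0, 0.0, 0.0, advection="upwind")
            c = _axial_rhs(u, v, grid, tab, 400.0, 0.0, 0.0, advection="central")
            diffs.append(np.abs(a - c).max())
        assert diffs[1] < diffs[0]
        assert diffs[1] < 0.2 * np.abs(u).max()


class TestContinuityReconstruction:
    def test_recovers_divergence_free_radial_velocity(self):
        """v built from u matches the analytic stream-function velocity field.

        With psi(r, z) = psihat(r/h) s(z), the pair u = (1/r) dpsi/dr,
        v = -(1/r) dpsi/dz satisfies continuity exactly; the trapezoidal
        reconstruction must converge to v at second order.
        """
        geom = StenosisGeometry(lambda_=0.3, l=2.0, d=3.0)

        def fields(grid):
            X, Z = np.meshgrid(grid.x, grid.z)
            h = geom.wall_radius(grid.z)[:, None]
            dh = geom.wall_slope(grid.z)[:, None]
            s = 1 + 0.3 * np.sin(Z)
            ds = 0.3 * np.cos(Z)
            psihat = X**2 * (1 - X**2 / 2)
            dpsihat = 2 * X - 2 * X**3
            u = 2 * (1 - X**2) * s / h**2
            with np.errstate(divide="ignore", invalid="ignore"):
                v = -(psihat * ds - X * dh / h * dpsihat * s) / (X * h)
            v[:, 0] = 0.0
            return u, v

        errs = []
        for mn in (40, 80):
            grid = Grid(M=mn, N=mn, domain_length=10.0, dt=1e-3)
            u, v_exact = fields(grid)
            tab = _tables(grid, geom, junction_rounding=0.0)
            v_rec = _reconstruct_v(u, grid, tab)
            # compare away from junction columns and the one-sided wall cell
            zmask = (grid.z > 3.2) & (grid.z < 4.8)
            err = np.abs(v_rec[zmask, 1:-1] - v_exact[zmask, 1:-1]).max()
            errs.append(err / np.abs(v_exact[zmask, 1:-1]).max())
        assert errs[0] < 0.12
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.3)


class TestRadialMomentumResidual:
    def test_zero_flow_gives_zero_residual(self, default_geometry):
        grid = Grid(M=20, N=20, dt=0.005)
        cfg = SolverConfig()
        s0 = initialize(grid, default_geometry)
        s1 = step(s0, grid, default_geometry, PressureForcing(p0=0, p1=0, omega=0),
                  BodyAcceleration(a0=0, omega=0), cfg)
        res = radial_momentum_residual(s0, s1, grid, default_geometry, cfg)
        assert np.abs(res).max() == 0.0

    def test_solution_residual_below_scrambled_residual(self, default_geometry):
        """The evolved flow honours radial momentum far better than noise."""
        grid = Grid(M=30, N=30, dt=0.005)
        cfg = SolverConfig()
        state = initialize(grid, default_geometry)
        pr, bo = PressureForcing(), BodyAcceleration()
        for _ in range(199):
            state = step(state, grid, default_geometry, pr, bo, cfg)
        nxt = step(state, grid, default_geometry, pr, bo, cfg)
        res = np.abs(radial_momentum_residual(state, nxt, grid, default_geometry, cfg)).max()

        rng = np.random.default_rng(0)
        noisy = FlowState(
            state.u + 0.1 * rng.standard_normal(state.u.shape),
            state.v + 0.1 * rng.standard_normal(state.v.shape),
            t=state.t,
            n=state.n,
        )
        noisy_next = FlowState(nxt.u.copy(), nxt.v.copy(), t=nxt.t, n=nxt.n)
        res_noisy = np.abs(
            radial_momentum_residual(noisy, noisy_next, grid, default_geometry, cfg)
        ).max()
        assert res < 0.1 * res_noisy

    def test_non_consecutive_states_rejected(self, default_geometry):
        grid = Grid(M=20, N=20, dt=0.005)
        s0 = initialize(grid, default_geometry)
        with pytest.raises(ValueError, match="consecutive"):
            radial_momentum_residual(s0, s0, grid, default_geometry, SolverConfig())
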