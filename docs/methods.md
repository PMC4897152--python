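# Methods

## Physical model

The arterial segment is a rigid axisymmetric cylinder of radius `r0`
carrying an incompressible Newtonian fluid (blood at the high shear rates
of the large arteries behaves approximately Newtonian).  All quantities are
nondimensional: lengths by `r0`, velocities by the mean speed `u_inf`
implied by the Reynolds number `Re = r0 u_inf / nu`, time by `r0 / u_inf`.
Two constrictions narrow the wall on `z in [d, d + 2l]`:

    h(z) = 1 - lambda cos(pi z / l),  d     <= z < d + l
    h(z) = 1 + lambda cos(pi z / l),  d + l <= z <= d + 2l
    h(z) = 1                          otherwise.

The profile is continuous exactly when `cos(pi d / l) = 0`; the constructor
rejects constricted geometries that violate this.  Its *slope*, however, is
discontinuous at `z = d, d + l, d + 2l` for any admissible parameters — the
two cosine bumps meet in corners.  The default (`lambda = 0.5, l = 2,
d = 3, L = 10`) puts the throats at `z = 4` and `z = 6` with the lumen
halved there.

The flow is driven by a prescribed spatially uniform axial pressure
gradient `-dp/dz = p0 + p1 cos(omega t)` and an optional axial body force
`F_ext = a0 cos(omega t + phi)` modelling whole-body acceleration.  The
radial pressure gradient is neglected (long slender tube).  The radial
transformation `x = r / h(z)` maps the lumen onto the fixed rectangle
`x in [0, 1], z in [0, L]`; the transformed continuity and momentum
equations (with metric terms in `h`, `h'`, `h''`) are written out in the
`solver` module docstring.  They were re-derived symbolically from the
cylindrical-coordinate equations, and the test suite pins the discrete
operators to that derivation (`TestOperatorConsistency`).

**Known structural defect of the model.**  Because the pressure gradient is
prescribed rather than solved, global mass conservation does not hold: the
flux `Q(z, t)` genuinely varies along the tube (the flux dips around the
throats are a *feature* of this model class).  Radially integrating
continuity then yields a nonzero radial velocity at the wall; the no-slip
condition overrides it, leaving a one-cell "defect sublayer" on the
stenosis flanks where the wall shear stress is resolution-limited.  Cross-
grid comparisons are therefore made on shared lattice nodes rather than by
interpolating through that layer.

## Default study conditions

| parameter | default | meaning |
|---|---|---|
| `lambda`, `l`, `d`, `L` | 0.5, 2, 3, 10 | geometry above (throats at z = 4, 6) |
| `Re` | 400 (also 600, 800) | Reynolds number |
| `p0`, `p1` | 0.1, 0.2·p0 | steady / pulsatile pressure-gradient amplitudes |
| `omega` | 0.8 | pulse angular frequency (nondimensional, see below) |
| `a0`, `phi` | p0, 0 | body-acceleration amplitude and phase |
| grid, `dt`, `t_end` | 60×60, 0.01, 10 | discretization of the base case |

`omega = 0.8` follows from a 72 beats/min pulse (f = 1.2 Hz) scaled with
`r0 = 1.2 cm` (aortic scale), `rho = 1.05 g/cm^3`, `mu = 0.035 P`:
`u_inf = Re nu / r0 ≈ 11 cm/s` at Re = 400 and `omega = 2 pi f r0 / u_inf
≈ 0.8`, i.e. a Womersley number `alpha = sqrt(omega Re) ≈ 17.9`, the upper
physiological range.  Two constraints anchor this choice: the pulse phase
must not be degenerate at the `t = 10` reporting time, and the
body-force velocity contribution `~ a0/omega` must keep `max |u|` within
the advective CFL limit of the 60×60, `dt = 0.01` base discretization —
much smaller `omega` (larger `a0/omega`) would make the base case
unintegrable by any explicit scheme, contradicting the premise that those
settings are convergent.  With the defaults the body force raises the peak
centreline velocity by ≈ 12% at `t = 10`.

`a0 = p0` keeps the body-acceleration effect clearly visible; `phi = 0`
puts it in phase with the pressure pulse.  `PhysicalScales` converts
nondimensional outputs (e.g. wall shear stress in units of
`mu u_inf / r0`) back to CGS.

## Numerical scheme

Forward Euler in time on the node-centred lattice `z_i = i dz`,
`x_j = j dx`.  Viscous, metric and mixed (`u_xz`) derivatives use central
differences.  The axial velocity is advanced from the transformed axial
momentum equation; the radial velocity is *reconstructed* at the new level
by trapezoidal integration of the transformed continuity equation outward
from the axis, which makes the discrete continuity residual vanish to
rounding error at every interior cell (asserted at 1e-10 in the tests).
The transformed radial momentum equation is implemented only as a residual
diagnostic (`radial_momentum_residual`): advancing v from it is impossible
anyway (every term carries v, so v would remain identically zero), and the
continuity route is the standard closure for this model family.

Boundary conditions after every step: `u = v = 0` at the wall; `v = 0` and
the discrete symmetry `u[:, 0] = u[:, 1]` on the axis (the `1/x` terms are
never evaluated there); zero axial gradient (copied nodes) at the inlet and
outlet, since the tube is straight and the flow fully developed far from
the stenoses.

**Advection.**  A fully centred explicit discretization of the advective
terms is linearly unstable here once `max |u| > sqrt(2 / (Re dt))` — about
0.7 at the default `dt = 0.01`, which the pressure-driven start-up crosses
before `t = 10`; in experiments it either blew up or saturated with O(1)
grid-scale oscillations at every grid/step combination of interest.  The
default scheme therefore upwinds the advective group (written with the
combined transformed velocities `c_x = (v - x u h')/h` and `c_z = u`):
second-order linear upwind along z (first-order fallback on the rows beside
the inlet/outlet) and donor-cell along x.
`SolverConfig(advection="central")` restores the fully centred stencils for
small-velocity work and scheme comparisons.  Both variants coincide
wherever the advective terms vanish — in particular in every straight-tube
benchmark (z-invariant fields, `v = 0`), so the Poiseuille/Womersley
validations exercise the untouched central operators.

**Corner rounding.**  The wall-slope jumps at the three stenosis junctions
inject O(1) truncation noise into the reconstructed v.  The solver's metric
tables `(h, h', h'')` therefore blend each corner with a C1 cubic Hermite
over a fixed physical half-width (`junction_rounding`, default 0.4 tube
radii, i.e. ≈ 2.4 cells of the 60×60 grid), so coarse and fine grids
discretize the *same* regular geometry.  Setting it to 0 recovers the raw
one-sided derivatives.  The public geometry methods always evaluate the
exact piecewise formulas.

**Stability.**  `stability_bound` combines the diffusive FTCS bound
`(Re/2) / ((h_min dx)^-2 + dz^-2)` with per-direction Courant bounds from
the current velocity field, scaled by a safety factor (default 0.9);
`simulate` warns (never aborts) when `dt` exceeds it.  Divergence (non-
finite fields or `max |u|` beyond a threshold) raises `BlowUpError` naming
the step.  The scheme is deterministic: identical configurations produce
bit-identical outputs, recorded with content hashes in the run manifest.

## Analytic benchmarks

The straight tube (`lambda = 0`) admits closed forms used as independent
oracles:

* steady: `u = (p0 Re / 4)(1 - x^2)`; centreline `p0 Re / 4`, flux
  `pi p0 Re / 8`, wall shear `p0 Re / 2`;
* oscillatory: the Womersley solution
  `Re{(p1/(i omega))[1 - J0(i^{3/2} alpha x)/J0(i^{3/2} alpha)] e^{i omega t}}`
  with `alpha = sqrt(omega Re)` (the momentum equation carries `1/Re` on
  the viscous term), superposed on the steady part.  An independent test
  verifies this formula against the PDE with high-order finite differences.

Two protocol details, chosen because straight-tube runs are *exactly*
z-invariant in floating point (every axial row undergoes identical
operations):

* benchmark runs use a small axial node count (M = 8–10) and, for steady
  runs, a larger `dt` (0.04 at N = 60) that still sits inside the diffusive
  bound — the discrete steady state is a fixed point independent of `dt`;
* the periodic (Womersley) validation *starts on the analytic solution* and
  measures the error accumulated over five forcing periods.  Starting from
  rest would measure the physical start-up transient instead, which decays
  like `exp(-j01^2 t / Re)` (time constant ≈ 69 time units ≫ 5 periods)
  and has nothing to do with scheme accuracy.

Measured with the defaults: centreline/flux errors < 0.1%, wall shear
≈ 0.8% (the one-sided wall difference is first-order), periodic Womersley
error ≈ 0.03%, steady-error ratio between N = 60 and N = 120 ≈ 3.6
(nominally second order; the axis closure contributes a weak log factor).

## Observables

Trapezoidal quadrature throughout, matching the scheme's discrete flux
definition: flux `Q = 2 pi h^2 ∫ x u dx`, Stokes stream function
`psi = h^2 ∫_0^x x' u dx'` (so `2 pi psi(wall) = Q` holds exactly, by
shared quadrature, not just to discretization error), wall shear stress
`tau = -(mu/h)(u_N - u_{N-1})/dx` with `mu = 1` in code units.

## What the default run shows — and what it does not

At `t = 10` the flow is still developing: the viscous penetration depth
`sqrt(t / Re) ≈ 0.16` is well below even the throat radius 0.5, so the core
is a nearly uniform plug.  Consequences, all reproduced by the tests:

* wall shear stress concentrates on the constrictions (throat values grow
  monotonically with Re over {400, 600, 800});
* the flux dips just downstream of each throat; radial inflow (`v < 0`)
  appears in the converging sections;
* the in-phase body force raises the peak centreline velocity by ≈ 12%;
* the 60×60/`dt = 0.01` and 100×100/`dt = 0.001` runs agree to ≈ 3.8%
  (max difference on shared nodes).

What does *not* occur at `t = 10`: dips of the centreline velocity at the
throats.  The inviscid core is uniform to < 1e-3 there; off-axis velocity
dips exist but sit ~0.7 radii downstream of the throats.  Centreline
minima at the throats only develop near the steady state — where, in turn,
the wall-shear maxima invert (under a prescribed gradient the steady wall
shear is `p0 Re h / 2 ∝ h`, lowest at the throats).  The two signatures are
mutually exclusive in this model; the corresponding acceptance test asserts
the developing-flow claim as stated and documents the discrepancy.

## Limitations

* Rigid walls, axisymmetry, Newtonian rheology, prescribed pressure
  gradient: no fluid–structure interaction, no non-Newtonian or
  magnetohydrodynamic effects, no 3-D/asymmetric flow.
* The prescribed-gradient closure breaks global mass conservation; wall
  shear on the stenosis flanks is resolution-limited (defect sublayer).
* Forward Euler is first-order in time; the upwinded advection is
  first-order in x near steep layers.  The scheme targets the moderate-Re
  developing flows of the study conditions, not turbulence or long-time
  vortex dynamics.
* `t = 10` snapshots probe the developing regime; conclusions about
  steady-state haemodynamics require `run_to_steady` and differ
  qualitatively (see above).
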