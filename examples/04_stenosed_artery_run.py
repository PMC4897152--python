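"""The full study case: pulsatile flow through the double stenosis.

Runs the default configuration (Re = 400, 60 x 60 grid, dt = 0.01, t = 10,
heartbeat pressure pulse plus an in-phase body-acceleration force) and its
body-acceleration-off counterpart, then reports the haemodynamic
observables a vascular modeller looks at: where the wall shear stress
peaks, where the flux dips, and how much the body force speeds up the flow.
"""

import numpy as np

from stenoflow import RunConfig, flow_rate, run_config, wall_shear_stress

cfg = RunConfig()
run = run_config(cfg, snapshot_interval=0.5)
run_off = run_config(cfg.without_body_acceleration(), snapshot_interval=0.5)

grid, geom = run.grid, run.geom
final = run.final
tau = wall_shear_stress(final, grid, geom)
q = flow_rate(final, grid, geom)

print(f"final time t = {final.t:g} after {final.n} steps; max |u| = {np.abs(final.u).max():.4f}")

for lo, hi, throat in [(3.0, 5.0, 4.0), (5.0, 7.0, 6.0)]:
    m = (grid.z >= lo) & (grid.z <= hi)
    z_tau = grid.z[m][np.argmax(tau[m])]
    z_q = grid.z[m][np.argmin(q[m])]
    print(f"stenosis with throat at z = {throat}:")
    print(f"  wall shear peaks at z = {z_tau:.2f} (tau = {tau[m].max():.2f})")
    print(f"  flux dips at       z = {z_q:.2f} (Q = {q[m].min():.3f})")

peak_on = max(s.u[:, 0].max() for s in run.snapshots)
peak_off = max(s.u[:, 0].max() for s in run_off.snapshots)
print(f"peak centerline velocity: {peak_on:.4f} with body acceleration, "
      f"{peak_off:.4f} without (+{100 * (peak_on - peak_off) / peak_off:.1f}%)")

# The wall shear stress concentrates on the constrictions (an order of
# magnitude above the straight-tube value), the flux is depressed around the
# throats, and the in-phase body acceleration boosts the core velocity by
# roughly a0/omega at this snapshot phase.
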