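"""A random 10-patch pattern self-organising into the regular state.

Integrates the pulse-location ODE at constant rainfall and prints the
decay of the gap coefficient of variation - the regularity indicator
that later decides whether a drying transition removes one patch or
half of them.
"""

import numpy as np

import drypatch as dp
from drypatch.reduction import integrate_pulse_ode, pulse_velocities

p = dp.NondimParams(a=0.5, m=0.45, D=0.01)
cfg = dp.random_pattern(10, 20.0, seed=7)
print("initial gaps:", np.round(cfg.gaps(), 2))
print(f"initial gap cv: {dp.gap_statistics(cfg).cv:.3f}")

traj = integrate_pulse_ode(cfg, p, t_end=1.5e5, n_samples=16)
for i in range(0, len(traj.ts), 3):
    c = traj.configuration_at(i)
    print(f"t = {traj.ts[i]:9.0f}   gap cv = {dp.gap_statistics(c).cv:.2e}")

final = traj.final_configuration()
vmax = np.max(np.abs(pulse_velocities(final, p).velocities))
print(f"final gaps: {np.round(final.gaps(), 4)}   max |velocity| = {vmax:.2e}")
print()
print("Patches migrate toward equal spacing (the attractor of the N-patch")
print("phase portrait); the exponential decay of the gap cv means a slowly")
print("drying ecosystem reaches the regular - most drought-resilient -")
print("arrangement long before rainfall becomes critical.")
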