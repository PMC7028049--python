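# drypatch

Pulse dynamics and resilience analysis for patterned dryland vegetation.

In water-limited ecosystems, vegetation self-organises into isolated
patches separated by bare soil.  `drypatch` implements the
pulse-interaction framework for the extended Klausmeier model

    w_t = w_xx + (s w)_x + a − w − w v²
    v_t = D² v_xx − m v + w v²

(water `w`, biomass `v`, rainfall `a`, mortality `m`, diffusion ratio
`D ≪ 1`): because plants disperse far more slowly than water
redistributes, an N-patch state is fully described by its patch
positions, and the infinite-dimensional PDE collapses onto the
pulse-location ODE

    dp_j/dt = (D / 6 m^{3/2}) · [w_x(p_j⁺)² − w_x(p_j⁻)²],

with the water slopes taken from closed-form profiles on the bare gaps.
Each patch absorbs flux `F_j`, holds water `w_j = 6Dm^{3/2}/F_j` and
carries biomass `B_j = F_j/m`.  On top of this the package provides

- a positivity-preserving IMEX solver for the full PDE with patch
  detection and loss-event tracking (`drypatch.pde`),
- numerical feasibility analysis: quasi-steady N-pulse states, sparse
  spectra, critical rainfall values `a_c,N` and the two resilience
  margins — ecological `a − a_c,N` and engineering `−max Re λ`
  (`drypatch.stability`),
- climate-ramp scenario engines (full PDE, or the fast hybrid
  ODE-plus-instantaneous-loss engine) with pre-emptive patch-removal
  conservation policies (`drypatch.scenarios`),
- seeded generators for regular and random patch configurations
  (`drypatch.patterns`) and a YAML-config CLI (`drypatch …`).

The central scientific content: patches migrate toward the equidistant
arrangement; regular patterns survive to lower rainfall but then lose
half their patches at once (period doubling), while irregular patterns
shed their weakest patch one at a time — so the *rate* of climate
change, through the time it leaves for regularisation, selects between
sporadic large transitions and a rapid cascade of small ones, and the
gap-spacing variance predicts which transition is imminent.

## Worked example

```python
import numpy as np
import drypatch as dp

p = dp.NondimParams(a=0.5, m=0.45, D=0.01)

# an uneven pair of patches on a periodic transect of length 8
cfg = dp.PulseConfiguration(domain_length=8.0, positions=np.array([2.0, 4.0]))
vel = dp.pulse_velocities(cfg, p)
print(vel.velocities)           # [-0.00056607  0.00056607]

budget = dp.patch_water_and_biomass(cfg, p)
print(budget.biomass.sum())     # 3.9020...

f = dp.simulate(dp.field_from_pulses(cfg, p), p, t_end=150.0).final
print(dp.total_biomass(f))      # 3.812... (PDE agrees within ~2%)
```

The velocities say each patch drifts at 5.7·10⁻⁴ space units per time
unit toward its wider gap (where the inter-patch water profile delivers
more flux); the reduced biomass 3.90 and the PDE's 3.81 agree to the
accuracy of the bare-soil boundary approximation.  Running
`python examples/04_slow_fast_dichotomy.py` reproduces the headline
dichotomy from 8 random patches: the fast ramp (T = 2·10³) loses all
patches one by one starting at a ≈ 0.30, while the slow ramp (T = 10⁵)
first regularises (gap cv 0.5 → 10⁻⁴) and then halves 8 → 4 → 2 at
a ≈ 0.225, persisting to lower rainfall.  The `examples/` directory has
one short script per capability.

## Layout

```
src/drypatch/
  params.py      parameter sets, scalings, climate ramps, rate classification
  patterns.py    patch configurations, gap statistics, field construction
  reduction.py   gap water profiles, pulse-location ODE, patch budgets
  pde.py         IMEX solver, patch detection, transition events
  stability.py   quasi-steady states, spectra, a_c_N, resilience metrics
  scenarios.py   climate-ramp engines, removal policies, comparisons
  io.py, cli.py  YAML configs, CSV/manifest output, `drypatch` CLI
examples/        one narrative script per capability
docs/methods.md  model, assumptions, numerical choices, limitations
```
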