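"""Slow versus fast climate change from the same irregular start.

Runs the hybrid engine (pulse ODE + instantaneous calibrated losses)
for a slow (T = 1e5) and a fast (T = 2e3) drying ramp from 8 randomly
placed patches, and summarises the dichotomy.  The first run includes a
one-off feasibility calibration (~half a minute).
"""

import drypatch as dp
from drypatch.scenarios import ScenarioSpec, dichotomy_report, run_scenario

p = dp.NondimParams(a=0.5, m=0.45, D=0.01)
init = dp.random_pattern(8, 16.0, seed=5)
print(f"initial gap cv: {dp.gap_statistics(init).cv:.3f}")

slow = run_scenario(ScenarioSpec(init, p, dp.ClimateRamp(0.5, 0.0, 1e5), engine="hybrid"))
fast = run_scenario(ScenarioSpec(init, p, dp.ClimateRamp(0.5, 0.0, 2e3), engine="hybrid"))

for name, res in (("slow", slow), ("fast", fast)):
    print(f"\n{name} ramp events:")
    for e in res.events:
        print(f"  a = {e.a_event:.3f}   {e.n_before} -> {e.n_after}   {e.type}")

rep = dichotomy_report(slow, fast)
print(f"\nfraction of single-patch losses: fast {rep['fast']['frac_single']:.2f}, "
      f"slow {rep['slow']['frac_single']:.2f}")
print(f"rainfall at first loss: slow {rep['slow']['a_first_loss']:.3f}, "
      f"fast {rep['fast']['a_first_loss']:.3f}")
print(f"biomass-curve crossings ('snaking'): {rep['biomass_crossings']}")
print()
print("Slow change lets patches regularise, so they persist to lower")
print("rainfall and then lose half their number at once; fast change")
print("freezes the irregular arrangement, which sheds its weakest patch")
print("one drying step at a time.")
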