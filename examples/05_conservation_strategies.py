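"""Pre-emptive patch removal as a conservation strategy.

Compares an unassisted slow-drying run of a regular 9-patch pattern
(which halves naturally) with removing every third patch just before
the destabilisation.
"""

import drypatch as dp
from drypatch.scenarios import RemovalPolicy, ScenarioSpec, compare_strategies

p = dp.NondimParams(a=0.5, m=0.45, D=0.01)
base = ScenarioSpec(dp.regular_pattern(9, 18.0), p,
                    dp.ClimateRamp(0.5, 0.0, 1e5), engine="hybrid")

table, results = compare_strategies(
    base,
    {
        "none": RemovalPolicy("none"),
        "every3": RemovalPolicy("every_kth", k=3, trigger=("at_margin", 0.02)),
    },
)
print(table.round(4).to_string())
print()
for name, res in results.items():
    print(f"{name}:")
    for e in res.events:
        tag = "removal" if e.manual else e.type
        print(f"  a = {e.a_event:.3f}   {e.n_before} -> {e.n_after}   {tag}")
print()
print("Sacrificing N/3 patches instead of suffering the natural loss of")
print("N/2 roughly halves the biomass drop at the first destabilisation;")
print("the price is that the thinned pattern meets its own next threshold")
print("at a higher rainfall value.")
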