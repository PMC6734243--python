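"""Enumerate all optimal pathways plus two sub-optimal levels.

Uses the methyl acetate worked network.  Levels are successive next-best
objective values, so they may skip lengths: here the optimum has 2 steps,
level 1 has two 3-step routes, and level 2 jumps to a single 5-step route
from valine.
"""

from retroflux.enumeration import enumerate_pathways
from retroflux.fixtures_oracle import published_fixture

fx = published_fixture("F-MACET")
state = enumerate_pathways(fx.db, fx.scope, fx.target, k=2)

print(f"target: {fx.target}  beta* = {state.beta_star}")
for level, pathways in enumerate(state.found):
    obj = state.level_objectives[level]
    print(f"level {level} (length {obj}): {len(pathways)} pathway(s)")
    for p in pathways:
        print("   " + " -> ".join(p.reactions))
# total pathways across levels = 4; every route shares the final
# acetone -> methyl acetate esterification step.
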