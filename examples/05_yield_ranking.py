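"""Rank enumerated pathways by FBA-predicted theoretical yield.

Each candidate pathway is integrated into a small chassis flux model with a
target exchange, carbon uptake is fixed, and the target exchange flux is
maximised; yield is mol target per mol carbon source.
"""

from retroflux import flux_analysis as fa
from retroflux.enumeration import enumerate_pathways
from retroflux.fixtures_oracle import published_fixture

fx = published_fixture("F-2PROH")
state = enumerate_pathways(fx.db, fx.scope, fx.target, k=1)
chassis = fa.chassis_for_scope(fx.db, fx.scope, uptake=10.0)

results = []
for i, p in enumerate(sorted(state.all_pathways, key=lambda p: p.reactions)):
    model = fa.integrate_pathway(chassis, p, fx.db, fx.target)
    results.append(
        fa.compute_yield(
            model, fx.target, "EX_acetoacetate", 10.0,
            pathway_id=f"route-{i}", pathway_length=p.length,
        )
    )

for r in fa.rank_pathways(results):
    print(f"{r.pathway_id}: length={r.pathway_length} yield={r.yield_:.2f} mol/mol")
# On this toy chassis every route converts precursor 1:1, so yields tie at
# 1.00 and the ranking falls back to pathway length (shortest first).
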