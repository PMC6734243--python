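"""Find the minimum set of non-native reaction additions for one target.

Loads the 2-propanol worked network (acetoacetate, farnesyl diphosphate and
methylglyoxal are native to the chassis) and solves the MILP once.  The
printed selection is the smallest set of heterologous reactions that lets
the chassis produce the target.
"""

from retroflux.fixtures_oracle import published_fixture
from retroflux.milp_core import build_system, solve_min_steps

fx = published_fixture("F-2PROH")
system = build_system(fx.db, fx.scope, fx.target, max_len=10)
res = solve_min_steps(system)

print(f"target: {fx.target}")
print(f"minimum additions (beta*): {res.objective}")
for v in sorted(res.selected_nonnative):
    r = fx.db.reactions[v]
    print(f"  {v}: {r.equation()}  [{r.enzyme or 'no EC'}]")
# beta* = 2: acetoacetate -> acetone -> 2-propanol, two enzyme additions.
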