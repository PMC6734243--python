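# retroflux

Pathway search for metabolic engineering: given a database of known
biological and chemical reactions and a **chassis organism** (the host
strain whose native metabolism supplies precursors), find **every** smallest
set of non-native reaction additions that enables production of a target
compound, continue through user-chosen *sub-optimal* levels (next-best
addition counts), and rank the candidate routes by FBA-predicted
theoretical yield.

This is the routing half of biological retrosynthesis.  Testing candidate
gene additions one by one with flux balance analysis explodes exponentially
with route length (a *y*-step route costs on the order of ḡ^y FBA calls,
with ḡ the mean number of producers per compound).  retroflux instead
solves one binary program per candidate and exhausts the solution space
with penalty reweighting and integer cuts, so the work scales with the
number of genuinely independent pathways, not with database size.

## The model

The database is a stoichiometric system over binary indicators
x ∈ {0,1}ⁿ, one per direction-split reaction.  The base problem is

    minimize  z = tᵀx
    s.t.      (producers − consumers of c) · x ≥ 0   for every non-native compound c
              (producers − consumers of g) · x ≥ 1   for the target g
              Σ_E x ≤ L                              (pathway-length cap, default L = 10)

Native compounds are unconstrained inputs (their rows are dropped); the
weight vector t is 0 on native reactions (the *I* block) and 1 on
non-native reactions (the *E* block), so z counts heterologous additions.
Coefficients in the availability rows are sign-binarised (±1) because x is
presence/absence, not flux.

Three mechanisms complete the engine:

* **All optima.**  After each discovered optimum of length β\*, the weights
  of its variables are raised to 1 + 1/(2β\*).  Any not-yet-found optimal
  pathway then still costs < β\*(1 + 1/(2β\*)) < β\*+1, while re-finding a
  known pathway costs exactly the bound — so iterating until the modified
  objective reaches β\*(1 + 1/(2β\*)) provably yields every optimal
  pathway.  Bound comparisons use exact rational arithmetic.
* **Sub-optimal levels.**  Each found pathway O contributes an integer cut
  Σ_{O} x ≤ |O|−1; re-running the all-optima loop under the accumulated
  cuts surfaces the next-best objective (levels may skip lengths).
* **Cycle exclusion.**  A selection can satisfy the counting balance as a
  closed loop with no real source; candidates with no topological
  production order from native compounds are cut and never reported.

Found pathways are backtracked into a bipartite compound/process
dependency graph; each pathway is a minimal connected subgraph in which
every retained non-native compound keeps a producer.  For ranking, each
pathway is grafted into a chassis flux model with a target exchange and a
two-LP scheme reports maximum biomass and maximum target flux at fixed
carbon uptake (yield in mol/mol).

## Worked example

```python
from retroflux.enumeration import enumerate_pathways
from retroflux.fixtures_oracle import published_fixture

fx = published_fixture("F-MACET")          # methyl acetate network
state = enumerate_pathways(fx.db, fx.scope, fx.target, k=2)
for level, pathways in enumerate(state.found):
    print(level, state.level_objectives[level],
          [" -> ".join(p.reactions) for p in pathways])
```

prints

```
0 2 ['R_adc -> R_bvmo']
1 3 ['R_fpp_1 -> R_fpp_2 -> R_bvmo', 'R_mgx_1 -> R_mgx_2 -> R_bvmo']
2 5 ['R_vox -> R_vx_1 -> R_vx_2 -> R_vx_3 -> R_bvmo']
```

— one 2-step optimum (acetoacetate → acetone → methyl acetate), two 3-step
level-1 alternatives (from farnesyl diphosphate and from methylglyoxal),
and a 5-step level-2 route from valine; every route shares the final
esterification step, and level 2 legitimately skips length 4.

The `examples/` directory holds one short script per capability (minimum
additions, sub-optimal levels, merging user reactions, dependency graphs
and DOT export, FBA yield ranking, planted-network benchmarking), each
printing the numbers it computes.  A thin CLI wraps the same library:

```sh
retroflux fixtures --out fixtures
retroflux query --db fixtures/f_2proh.rfdb --scope fixtures/f_2proh.scope \
    --target 2-propanol -k 1 --fba --out results/
```

## Layout

```
src/retroflux/
  netdb.py            database + chassis scope, text format, SBML import
  milp_core.py        binary program construction and exact-objective solving
  enumeration.py      all-optima penalty loop, sub-optimal levels, cuts
  pathway_graph.py    dependency graph, subgraph extraction, verification
  flux_analysis.py    flux models, pathway integration, two-LP yield, ranking
  fixtures_oracle.py  worked networks, planted generator, brute-force oracle
  reporting.py, cli.py
```

See `docs/methods.md` for the model details, numerical choices and known
limitations.
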