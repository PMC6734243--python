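# Methods

## Problem and scope

retroflux answers one question: which sets of non-native (heterologous or
chemical) reactions, added to a chassis organism, enable net production of
a target compound — enumerated exhaustively from the smallest sets upward,
then ranked by FBA theoretical yield.  Enzyme discovery, reaction-rule
(SMARTS) prediction of novel chemistry, repository harvesting and
compound-identity reconciliation across databases are out of scope; the
database is taken as given, and compound identity is the id string.

## Data model

A database holds compounds and reactions with exact rational stoichiometry
(`fractions.Fraction`; parsers accept decimals and ratios).  Reactions are
stored once with a `reversible` flag; direction splitting is a solver
concern.  A chassis scope *declares* native compounds and native reactions
for one organism — nativeness is never inferred from topology, so a
compound produced by a native reaction may still be non-native.  Scopes can
be derived from an SBML model (every species native, boundary species
excluded by default; exchange-style one-sided pseudo-reactions keep their
native-reaction status but are not database reactions, which must have
both a substrate and a product).

The on-disk format is a versioned tab-separated text file with a canonical
writer (sorted ids, fixed field order), so `save(load(x)) == x` holds
byte-for-byte and fixtures diff cleanly.

## The binary program

Each reaction contributes one binary variable per usable direction
(reverse variables exist only for reversible reactions; `x_f + x_b ≤ 1`
forbids a reaction cancelling itself).  Rows:

* native compounds — unconstrained (rows dropped; this realises the
  "infinite availability" bound);
* every other compound c — `Σ producers(c) − Σ consumers(c) ≥ 0` over the
  selected variables, with **sign-binarised** ±1 coefficients;
* the target — same expression `≥ 1`;
* `Σ E-block ≤ max_len` (default 10) caps pathway length;
* accumulated integer cuts.

Sign binarisation rather than raw coefficients is deliberate: the
variables encode presence/absence, so with raw coefficients feasibility
would depend on arbitrary stoichiometric scaling of each reaction record.
The raw/binarised choice is isolated in one place
(`milp_core.MILPSystem._signs`) should a flux-weighted variant ever be
wanted.

Weights are 0 on native-reaction variables (they may assist by producing a
non-native intermediate but never count) and 1 on non-native variables.
Pathway identity is the selected non-native set only; selections that
differ in weight-0 variables are the same pathway.

**Solving.**  The backend is HiGHS (`scipy.optimize.milp`).  Rational
weights are scaled by their denominators' LCM to exact integers before the
solve, and the objective is recomputed exactly from the returned selection,
so every bound comparison in the enumeration layer is exact rational
arithmetic regardless of floating-point solver internals.  A second stage
pins the objective and minimises small per-variable index weights over
id-sorted variables — a deterministic, id-order-biased representative among
equal-objective optima (true lexicographic selection would need one solve
per variable; the index-weight scheme is one solve and deterministic, which
is what reproducibility needs).  Binary values are read back with a 0.5
threshold; all constraint coefficients are integers, so no further
tolerance enters.

## All-optima enumeration

With β\* the minimum number of additions, each found pathway's variables
are re-weighted from 1 to `w = 1 + 1/(2β*)`.  A not-yet-found optimal
pathway shares at most β\*−1 penalised variables and therefore costs at
most β\* + (β\*−1)/(2β\*) = β\* + 1/2 − 1/(2β\*), strictly below the
termination bound B = β\*·w = β\* + 1/2; a fully-penalised (known) pathway
costs exactly B, and any longer pathway costs ≥ β\*+1 > B.  The loop
accepts candidates until the modified optimum reaches B.  Consequences
used as invariants: every accepted level-0 pathway has raw length exactly
β\*; no pathway can be reported twice; the loop performs |found| + 1
solves plus one per cyclic exclusion.

**Cycle exclusion.**  The counting balance admits closed loops with no
source (e.g. A→B plus B→A+target: every intermediate nets ≥ 0 yet nothing
is ever producible from native inputs).  Every candidate is checked for a
topological production order by forward chaining from native availability;
orderless candidates receive a persistent integer cut and do not count
toward termination.  If all candidates at the current optimum turn out
cyclic, the level re-bases at the next objective value (weights are still
clean there, so the objective is integral).  Cyclic cuts persist across
levels — a source-less cycle is invalid at every level.  Note the cut also
forbids supersets of the cyclic set; this is consistent with the
minimality rule below (any superset of a counting-feasible set is
non-minimal) and keeps the MILP and the oracle in exact agreement.

## Sub-optimal levels

After level j, each found pathway O adds the cut `Σ_O x ≤ |O|−1`
(forbidding O and all supersets), weights reset to the clean E-block, and
the all-optima loop re-runs at the new best objective.  A "level" is the
next-best objective value, not β\*+j: the worked methyl acetate network
has levels of length 2, 3 and 5, skipping 4.  Stale penalties are never
carried across levels — the cuts already exclude prior levels, and
leftover penalties would distort the next level's bound.  Once a level is
empty, all deeper levels are empty and recorded as such.

## Dependency graph and verification

The union of variables over all found pathways is backtracked from the
target: attach producer processes of the current compound, remove them
from the pending pool, enqueue their non-native inputs; native compounds
are leaves.  Pathway extraction enumerates minimal process subsets such
that the target is produced, every retained non-native compound keeps a
producer, and the induced bipartite subgraph is connected ("at least one
predecessor per compound node" is applied to non-native compound nodes
only — native leaves need no producer).  Extraction is an independent
cross-check of enumeration, not a replacement.

`verify_pathway` is the package's independent feasibility oracle: counting
feasibility of the forced selection, optionally helped by native reactions
that touch non-native compounds (all subsets of that usually-empty helper
set are tried, guarded to 12).  `is_acyclic_pathway` is the production-order
check.  The brute-force oracle enumerates all variable subsets up to the
length cap and keeps verifier-feasible, minimal (no counting-feasible
proper subset), orderable sets — correctness over speed, guarded to 20
non-native reactions.

## Flux analysis

`FluxModel` is a minimal constraint-based model (rational stoichiometry,
flux bounds, steady state, one objective) solved with HiGHS
(`scipy.optimize.linprog`).  Pathway integration adds the selected
reactions irreversibly in their chosen direction with raw coefficients
(flux semantics, unlike the MILP's counting semantics) plus a target
exchange.  Yield uses two LPs: LP 1 maximises biomass; LP 2 fixes carbon
uptake at the requested basis, floors biomass at a configurable fraction
of LP 1's optimum (default 0) and maximises target exchange.  The fraction
knob spans the two readings of "optimise growth and production": 1
reproduces growth-coupled, 0 pure production.  A cobra/GLPK export exists
solely as an independent cross-check in the tests.  Published genome-scale
yields require external genome-scale models and are validated here only on
shipped toy chassis models, where closed-form answers exist (the 1:1 toy
yields exactly 1.0; a forced 50% biomass floor halves it).

## Fixtures and the planted generator

Eight worked networks encode published validation routes; intermediates
the route descriptions leave unnamed use documented placeholder ids, and
the tested surface is counts and lengths, never placeholder names.  Two
encoding choices worth noting: the isobutanol valine route is encoded
through its own intermediate rather than the native keto acid (encoded via
the keto acid it would be a superset of the 2-step optimum and correctly
excluded by the cuts — the published count of three distinct routes forces
the distinct-intermediate reading); and the 2-methylbutanal network carries
two dead-end distractor reactions so that pruning behaviour is exercised.

The random generator plants disjoint linear routes from distinct native
sources (level-0 truth by construction), adds dead-end distractors (which
can never shorten a route), optional reversible/chemical markings, and
source-less two-cycles feeding the target (counting-feasible, orderless —
exactly the pathological case cycle exclusion exists for).  Every generated
network is validated against the brute-force oracle before being returned.
Default study conditions for the seeded agreement suite
(`standard_benchmark_knobs`): depth 1–4, 1–3 optimal plants, 0–2
sub-optimal plants, 0–3 distractors, 0–2 cycles, reversibility on every
third seed, chemical steps on every fourth, always ≤ 15 non-native
reactions so the oracle remains exhaustive.

What the synthetic networks do **not** emulate: genome-scale size
(thousands of compounds), cofactor coupling and currency metabolites,
multi-substrate stoichiometry in planted routes, and realistic degree
distributions.  Passing the agreement suite shows algorithmic correctness
of the enumeration machinery, not performance or biological fidelity at
repository scale.

## Determinism and degenerate inputs

Identical configuration and seed give byte-identical JSON output (sorted
keys and stable orderings throughout; the tie-broken solver is
deterministic).  A native target yields the empty pathway of length 0 and
empty sub-optimal levels.  An unreachable target reports infeasibility
(distinct CLI exit code).  Duplicate ids, dangling references, zero
coefficients and one-sided reactions are rejected at construction.

## Known limitations

* Counting (presence/absence) semantics ignore stoichiometric yield during
  search; a route that needs 2 units of an intermediate per unit of target
  looks the same as a 1:1 route until the FBA stage.
* The oracle-backed guarantees hold at desk scale (≤ 20 non-native
  reactions); at larger scale the MILP machinery runs unchanged but without
  an exhaustive cross-check.
* `chassis_for_scope` builds a deliberately permissive toy chassis (every
  native compound importable); yields on it are upper bounds, not
  organism-realistic predictions.
* Multi-target runs are sequential; per-target isolation makes them
  trivially parallelisable, but no process pool is shipped.
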