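"""All-optima and sub-optimal pathway enumeration.

Level 0 (optimal) enumeration uses penalty reweighting: after each
discovered minimum-length pathway, the objective weights of its variables
are raised from 1 to ``1 + 1/(2*beta_star)``, which makes any pathway that
shares at least one not-yet-penalised variable still cost strictly less
than the termination bound ``beta_star * (1 + 1/(2*beta_star))`` while a
fully-penalised (already found) pathway costs exactly the bound.  The loop
therefore surfaces every alternative optimum before the modified objective
reaches the bound, at which point it terminates.  All bound comparisons are
exact rational arithmetic.

Sub-optimal levels 1..k are produced by adding one integer cut per found
pathway (selected count over the pathway's variable set <= length - 1,
which forbids the set and all its supersets), resetting the weights, and
re-running the all-optima procedure at the next-best objective value.  A
"level" is the next-best objective, not necessarily ``beta_star + level``:
successive levels may skip lengths.

Candidates that satisfy the counting balance but admit no topological
production order (closed cycles without a source) are excluded with a
persistent integer cut and never count toward termination.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .milp_core import (
    MILPSystem,
    SolveResult,
    SolveStatus,
    build_system,
    solve_min_steps,
)
from .netdb import ChassisScope, MetabolicDatabase
from .pathway_graph import is_acyclic_pathway

__all__ = [
    "Pathway",
    "IntegerCut",
    "EnumerationState",
    "EnumerationOverflowError",
    "enumerate_all_optimal",
    "enumerate_suboptimal",
    "enumerate_pathways",
    "exclude_cyclic",
]

DEFAULT_ITERATION_CAP = 1000


class EnumerationOverflowError(RuntimeError):
    pass


@dataclass(frozen=True)
class Pathway:
    """A set of non-native reaction-variable additions enabling the target.

    ``reactions`` is stored in topological production order when one exists
    (it always does for accepted pathways); identity is by set.
    """

    reactions: tuple[str, ...]
    level: int
    objective_at_discovery: Fraction

    @property
    def length(self) -> int:
        return len(self.reactions)

    @property
    def reaction_set(self) -> frozenset[str]:
        return frozenset(self.reactions)


@dataclass(frozen=True)
class IntegerCut:
    """Forbids one found selection (and its supersets): sum over O <= |O|-1."""

    variable_set: frozenset[str]

    @property
    def rhs(self) -> int:
        return len(self.variable_set) - 1


@dataclass
class EnumerationState:
    target: str
    max_len: int
    beta_star: int | None = None  # level-0 optimum, None if infeasible
    found: list[list[Pathway]] = field(default_factory=list)
    level_objectives: list[int | None] = field(default_factory=list)
    cuts: list[IntegerCut] = field(default_factory=list)
    cyclic_cuts: list[IntegerCut] = field(default_factory=list)
    solve_counts: list[int] = field(default_factory=list)
    terminal_objectives: list[Fraction | None] = field(default_factory=list)

    @property
    def penalty_weight(self) -> Fraction | None:
        if not self.beta_star:
            return None
        return 1 + Fraction(1, 2 * self.beta_star)

    @property
    def termination_bound(self) -> Fraction | None:
        if not self.beta_star:
            return None
        return self.beta_star * self.penalty_weight

    @property
    def union_variables(self) -> frozenset[str]:
        """S*_v: every variable appearing in any found pathway, all levels."""
        out: set[str] = set()
        for level in self.found:
            for p in level:
                out.update(p.reactions)
        return frozenset(out)

    @property
    def all_pathways(self) -> list[Pathway]:
        return [p for level in self.found for p in level]


def _topological_order(
    selection: frozenset[str], db: MetabolicDatabase, scope: ChassisScope
) -> tuple[str, ...]:
    from .pathway_graph import _var_stoich  # shared directed-stoichiometry helper

    remaining = set(selection)
    available = set(scope.native_compounds)
    order: list[str] = []
    progress = True
    while remaining and progress:
        progress = False
        for v in sorted(remaining):
            stoich = _var_stoich(v, db)
            if all(c in available for c, coef in stoich.items() if coef < 0):
                available.update(c for c, coef in stoich.items() if coef > 0)
                remaining.discard(v)
                order.append(v)
                progress = True
    if remaining:
        raise ValueError("selection admits no topological production order")
    return tuple(order)


def exclude_cyclic(system: MILPSystem, candidate: Pathway | frozenset[str]) -> IntegerCut:
    """Append a persistent integer cut forbidding a cyclic candidate."""
    vs = candidate.reaction_set if isinstance(candidate, Pathway) else frozenset(candidate)
    cut = IntegerCut(vs)
    system.add_cut(cut.variable_set, cut.rhs)
    return cut


def _run_level(
    system: MILPSystem,
    state: EnumerationState,
    level: int,
    iteration_cap: int,
) -> None:
    """Penalty-reweighting all-optima loop at the current cut set."""
    system.reset_weights()
    solves = 0
    res = solve_min_steps(system)
    solves += 1
    if res.status is not SolveStatus.optimal:
        state.found.append([])
        state.level_objectives.append(None)
        state.solve_counts.append(solves)
        state.terminal_objectives.append(None)
        return

    beta = int(res.objective)
    if beta == 0:
        # target native: unique empty pathway, nothing to penalise
        state.found.append([Pathway((), level, Fraction(0))])
        state.level_objectives.append(0)
        state.solve_counts.append(solves)
        state.terminal_objectives.append(Fraction(0))
        if level == 0:
            state.beta_star = 0
        return

    w_p = 1 + Fraction(1, 2 * beta)
    bound = beta * w_p
    found: list[Pathway] = []
    seen: set[frozenset[str]] = set()
    terminal: Fraction | None = None
    iterations = 0
    while True:
        iterations += 1
        if iterations > iteration_cap:
            raise EnumerationOverflowError(
                f"level {level}: exceeded {iteration_cap} iterations"
            )
        if res.status is not SolveStatus.optimal:
            terminal = None
            break
        if res.objective >= bound:  # exact Fraction comparison
            if found:
                terminal = res.objective
                break
            # every candidate at the previous optimum was cyclic and is now
            # cut; the level re-bases at the new optimum (weights are still
            # clean, so the objective is integral)
            assert res.objective.denominator == 1
            beta = int(res.objective)
            w_p = 1 + Fraction(1, 2 * beta)
            bound = beta * w_p
        sel = res.selected_nonnative
        raw_len = len(sel)
        if not is_acyclic_pathway(sel, system.db, system.scope):
            cut = exclude_cyclic(system, sel)
            state.cyclic_cuts.append(cut)
        else:
            assert raw_len == beta, (
                f"penalty loop surfaced length {raw_len} != level optimum {beta}"
            )
            assert sel not in seen, "duplicate pathway surfaced despite penalties"
            seen.add(sel)
            order = _topological_order(sel, system.db, system.scope)
            found.append(Pathway(order, level, res.objective))
            for v in sel:
                system.set_weight(v, w_p)
        res = solve_min_steps(system)
        solves += 1

    state.found.append(found if found else [])
    state.level_objectives.append(beta if found else None)
    state.solve_counts.append(solves)
    state.terminal_objectives.append(terminal)
    if level == 0 and found:
        state.beta_star = beta


def enumerate_all_optimal(
    system: MILPSystem, *, iteration_cap: int = DEFAULT_ITERATION_CAP
) -> EnumerationState:
    """Enumerate every minimum-length pathway (level 0)."""
    state = EnumerationState(target=system.target, max_len=system.max_len)
    _run_level(system, state, 0, iteration_cap)
    return state


def enumerate_suboptimal(
    state: EnumerationState,
    system: MILPSystem,
    k: int,
    *,
    iteration_cap: int = DEFAULT_ITERATION_CAP,
) -> EnumerationState:
    """Extend a completed level-0 enumeration with sub-optimal levels 1..k.

    Before each new level, one integer cut per pathway found at the previous
    level is added (cuts from earlier levels persist), the weights are reset,
    and the all-optima loop is re-run at the next-best objective.  Once a
    level comes back empty every deeper level is empty too and is recorded
    as such.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if not state.found:
        raise ValueError("state does not hold a completed level-0 enumeration")
    for level in range(len(state.found), k + 1):
        prev = state.found[level - 1]
        if not prev or (len(prev) == 1 and prev[0].length == 0):
            # previous level empty (exhausted) or native-target degenerate
            state.found.append([])
            state.level_objectives.append(None)
            state.solve_counts.append(0)
            state.terminal_objectives.append(None)
            continue
        for p in prev:
            cut = IntegerCut(p.reaction_set)
            system.add_cut(cut.variable_set, cut.rhs)
            state.cuts.append(cut)
        _run_level(system, state, level, iteration_cap)
        prev_obj = state.level_objectives[level - 1]
        new_obj = state.level_objectives[level]
        if new_obj is not None and prev_obj is not None:
            assert new_obj > prev_obj, "sub-optimal level objective did not increase"
    return state


def enumerate_pathways(
    db: MetabolicDatabase,
    scope: ChassisScope,
    target: str,
    *,
    k: int = 0,
    max_len: int = 10,
    iteration_cap: int = DEFAULT_ITERATION_CAP,
) -> EnumerationState:
    """Build the MILP system and enumerate levels 0..k in one call."""
    system = build_system(db, scope, target, max_len=max_len)
    state = enumerate_all_optimal(system, iteration_cap=iteration_cap)
    if k > 0:
        enumerate_suboptimal(state, system, k, iteration_cap=iteration_cap)
    return state
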