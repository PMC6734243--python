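"""Binary MILP for minimum-step pathway search.

The database is compiled into a binary program over direction-split reaction
indicator variables: minimise the number of selected non-native reactions
subject to per-compound availability constraints.  Native compounds are
unconstrained inputs (their rows are dropped), every other compound must be
net-produced (sign-binarised producers minus consumers >= 0), and the target
compound must be net-produced at least once.  Native reactions carry weight
0, non-native reactions weight 1; weights may later be raised by the
all-optima penalty scheme and integer cuts may be appended, both without
rebuilding the system.

The backend is HiGHS via :func:`scipy.optimize.milp`.  All weights are exact
rationals; they are scaled to integers before the solve and the objective is
recomputed exactly from the returned selection, so objective comparisons
elsewhere in the package are exact.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from math import lcm
from typing import Iterable

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, milp

from .netdb import ChassisScope, MetabolicDatabase, Reaction

__all__ = [
    "REVERSE_SUFFIX",
    "SplitVariable",
    "MILPSystem",
    "SolveResult",
    "SolveStatus",
    "TargetNotFoundError",
    "SolverBackendError",
    "split_variables",
    "directed_stoichiometry",
    "build_system",
    "solve_min_steps",
]

REVERSE_SUFFIX = "__rev"


class TargetNotFoundError(KeyError):
    pass


class SolverBackendError(RuntimeError):
    pass


class SolveStatus(enum.Enum):
    optimal = "optimal"
    infeasible = "infeasible"
    capped = "capped"


@dataclass(frozen=True)
class SplitVariable:
    """One binary indicator: a reaction used in one fixed direction."""

    var_id: str
    reaction_id: str
    forward: bool
    nonnative: bool  # True iff in the E-block (weight 1 at construction)


def split_variables(db: MetabolicDatabase, scope: ChassisScope) -> list[SplitVariable]:
    """Direction-split variables in deterministic (reaction id, fwd<rev) order."""
    out: list[SplitVariable] = []
    for rid in sorted(db.reactions):
        r = db.reactions[rid]
        nonnative = rid not in scope.native_reactions
        out.append(SplitVariable(rid, rid, True, nonnative))
        if r.reversible:
            out.append(SplitVariable(rid + REVERSE_SUFFIX, rid, False, nonnative))
    return out


def variable_reaction_id(var_id: str) -> str:
    return var_id[: -len(REVERSE_SUFFIX)] if var_id.endswith(REVERSE_SUFFIX) else var_id


def variable_is_forward(var_id: str) -> bool:
    return not var_id.endswith(REVERSE_SUFFIX)


def directed_stoichiometry(reaction: Reaction, forward: bool) -> dict[str, Fraction]:
    if forward:
        return dict(reaction.stoichiometry)
    return {c: -v for c, v in reaction.stoichiometry.items()}


@dataclass
class MILPSystem:
    """Compiled system: variables, compound rows, weights, accumulated cuts."""

    db: MetabolicDatabase
    scope: ChassisScope
    target: str
    max_len: int
    variables: list[SplitVariable]
    weights: dict[str, Fraction]
    cuts: list[tuple[frozenset[str], int]] = field(default_factory=list)
    trivial: bool = False  # target is native: optimum is the empty pathway

    def __post_init__(self) -> None:
        self._index = {v.var_id: i for i, v in enumerate(self.variables)}
        # directed sign-binarised stoichiometry per variable
        self._signs: dict[str, dict[str, int]] = {}
        for v in self.variables:
            stoich = directed_stoichiometry(self.db.reactions[v.reaction_id], v.forward)
            self._signs[v.var_id] = {c: (1 if coef > 0 else -1) for c, coef in stoich.items()}

    # -- introspection -----------------------------------------------------
    @property
    def e_block(self) -> list[str]:
        return [v.var_id for v in self.variables if v.nonnative]

    @property
    def constrained_compounds(self) -> list[str]:
        """Non-native compounds, each owning one row (the target row is >=1)."""
        return [
            c for c in self.db.compounds if not self.scope.is_native_compound(c)
        ]

    def sign(self, var_id: str, compound_id: str) -> int:
        return self._signs[var_id].get(compound_id, 0)

    # -- mutation used by the enumeration loop ----------------------------
    def set_weight(self, var_id: str, weight: Fraction) -> None:
        v = self.variables[self._index[var_id]]
        if v.nonnative and weight < 1:
            raise ValueError("E-block weights may only be raised, never below 1")
        self.weights[var_id] = Fraction(weight)

    def reset_weights(self) -> None:
        for v in self.variables:
            self.weights[v.var_id] = Fraction(1) if v.nonnative else Fraction(0)

    def add_cut(self, variable_set: Iterable[str], rhs: int | None = None) -> None:
        vs = frozenset(variable_set)
        if rhs is None:
            rhs = len(vs) - 1
        if rhs < 0:
            raise ValueError("integer cut rhs must be >= 0")
        self.cuts.append((vs, rhs))


@dataclass(frozen=True)
class SolveResult:
    status: SolveStatus
    objective: Fraction | None
    selected: frozenset[str]
    selected_nonnative: frozenset[str]


def build_system(
    db: MetabolicDatabase,
    scope: ChassisScope,
    target: str,
    max_len: int = 10,
) -> MILPSystem:
    """Compile (database, scope, target) into a ready-to-solve MILP system."""
    if target not in db.compounds:
        raise TargetNotFoundError(target)
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    scope.check_against(db)
    variables = split_variables(db, scope)
    weights = {
        v.var_id: (Fraction(1) if v.nonnative else Fraction(0)) for v in variables
    }
    return MILPSystem(
        db=db,
        scope=scope,
        target=target,
        max_len=max_len,
        variables=variables,
        weights=weights,
        trivial=scope.is_native_compound(target),
    )


def _assemble_constraints(system: MILPSystem) -> list[LinearConstraint]:
    n = len(system.variables)
    idx = {v.var_id: i for i, v in enumerate(system.variables)}
    rows: list[dict[int, float]] = []
    lbs: list[float] = []
    ubs: list[float] = []

    # compound availability rows (w-block >= 0, g-row >= 1)
    for cid in system.constrained_compounds:
        row = {
            idx[v.var_id]: float(s)
            for v in system.variables
            if (s := system.sign(v.var_id, cid)) != 0
        }
        lb = 1.0 if cid == system.target else 0.0
        if not row and lb == 0.0:
            continue  # untouched compound, vacuous
        rows.append(row)
        lbs.append(lb)
        ubs.append(np.inf)

    # reversible mutual exclusion x_f + x_b <= 1
    for v in system.variables:
        if not v.forward:
            rows.append({idx[v.reaction_id]: 1.0, idx[v.var_id]: 1.0})
            lbs.append(-np.inf)
            ubs.append(1.0)

    # pathway-length cap over the E-block
    rows.append({idx[vid]: 1.0 for vid in system.e_block})
    lbs.append(-np.inf)
    ubs.append(float(system.max_len))

    # accumulated integer cuts
    for vs, rhs in system.cuts:
        rows.append({idx[vid]: 1.0 for vid in vs})
        lbs.append(-np.inf)
        ubs.append(float(rhs))

    data, ri, ci = [], [], []
    for r, row in enumerate(rows):
        for c, val in row.items():
            ri.append(r)
            ci.append(c)
            data.append(val)
    a = sparse.csr_matrix((data, (ri, ci)), shape=(len(rows), n))
    return [LinearConstraint(a, np.array(lbs), np.array(ubs))]


def _run_milp(c: np.ndarray, constraints: list[LinearConstraint], n: int):
    res = milp(
        c=c,
        constraints=constraints,
        integrality=np.ones(n),
        bounds=(0, 1),
    )
    if res.status not in (0, 2):  # 0 success, 2 infeasible
        raise SolverBackendError(f"MILP backend failed: status={res.status} {res.message}")
    return res


def solve_min_steps(system: MILPSystem) -> SolveResult:
    """Solve for one minimum-weight selection under current weights and cuts.

    Two-stage solve: stage 1 finds the optimal objective; stage 2 pins the
    objective and minimises a small per-variable index weight over id-sorted
    variables, giving a deterministic, id-order-biased representative among
    equal-objective optima (and zeroing out free weight-0 variables).
    """
    if system.trivial and not system.cuts:
        return SolveResult(SolveStatus.optimal, Fraction(0), frozenset(), frozenset())

    n = len(system.variables)
    scale = lcm(*(w.denominator for w in system.weights.values())) if system.weights else 1
    c_int = np.array(
        [int(system.weights[v.var_id] * scale) for v in system.variables], dtype=float
    )
    constraints = _assemble_constraints(system)
    res = _run_milp(c_int, constraints, n)
    if res.status == 2:
        return SolveResult(SolveStatus.infeasible, None, frozenset(), frozenset())

    selected = frozenset(
        v.var_id for v, x in zip(system.variables, res.x) if x > 0.5
    )
    z_exact = sum((system.weights[vid] for vid in selected), Fraction(0))

    # stage 2: deterministic tie-break at the pinned optimum
    tie = np.array([float(i + 1) for i in range(n)])
    pin = LinearConstraint(
        sparse.csr_matrix(c_int.reshape(1, -1)), -np.inf, float(z_exact * scale)
    )
    res2 = _run_milp(tie, constraints + [pin], n)
    if res2.status == 0:
        selected = frozenset(
            v.var_id for v, x in zip(system.variables, res2.x) if x > 0.5
        )
        z_exact = sum((system.weights[vid] for vid in selected), Fraction(0))

    nonnative = frozenset(vid for vid in selected if vid in set(system.e_block))
    return SolveResult(SolveStatus.optimal, z_exact, selected, nonnative)
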