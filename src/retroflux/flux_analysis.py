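"""Flux-balance integration and theoretical-yield ranking of pathways.

A :class:`FluxModel` is a plain constraint-based model: reactions with
rational stoichiometry and flux bounds, steady-state mass balance on every
compound, and a designated objective reaction.  Exchange reactions follow
the usual convention (stoichiometry ``{compound: -1}``; negative flux is
uptake, positive flux secretion).

Yield is computed with a two-LP scheme: LP 1 maximises the biomass
objective; LP 2 fixes carbon uptake at the requested basis, requires
biomass at a configurable fraction of LP 1's optimum (0 by default), and
maximises the target exchange.  The reported yield is target flux divided
by the uptake basis (mol/mol).  LPs are solved with HiGHS via
:func:`scipy.optimize.linprog`; a cobra export is provided as an
independent cross-check route.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .milp_core import directed_stoichiometry, variable_is_forward, variable_reaction_id
from .netdb import ChassisScope, MetabolicDatabase

__all__ = [
    "FluxReaction",
    "FluxModel",
    "YieldResult",
    "IntegrationError",
    "eco_mini_model",
    "chassis_for_scope",
    "integrate_pathway",
    "remove_pathway",
    "compute_yield",
    "rank_pathways",
    "to_cobra_model",
]

DEFAULT_UB = 1000.0


class IntegrationError(ValueError):
    pass


@dataclass
class FluxReaction:
    id: str
    stoichiometry: dict[str, Fraction]
    lb: float = 0.0
    ub: float = DEFAULT_UB

    def __post_init__(self) -> None:
        self.stoichiometry = {c: Fraction(v) for c, v in self.stoichiometry.items()}
        if self.lb > self.ub:
            raise ValueError(f"{self.id}: lb > ub")


@dataclass
class FluxModel:
    """Steady-state constraint-based model with a designated objective."""

    reactions: dict[str, FluxReaction] = field(default_factory=dict)
    objective: str | None = None

    def copy(self) -> "FluxModel":
        return FluxModel(
            {rid: _copy.deepcopy(r) for rid, r in self.reactions.items()},
            self.objective,
        )

    @property
    def compounds(self) -> list[str]:
        out: set[str] = set()
        for r in self.reactions.values():
            out.update(r.stoichiometry)
        return sorted(out)

    def add_reaction(self, rxn: FluxReaction) -> None:
        if rxn.id in self.reactions:
            raise IntegrationError(f"reaction id {rxn.id!r} already in model")
        self.reactions[rxn.id] = rxn

    def add_exchange(self, compound: str, lb: float = 0.0, ub: float = DEFAULT_UB) -> str:
        rid = f"EX_{compound}"
        self.add_reaction(FluxReaction(rid, {compound: Fraction(-1)}, lb, ub))
        return rid

    def optimize(
        self,
        objective: str | None = None,
        *,
        fixed: Mapping[str, tuple[float, float]] | None = None,
        minimum: Mapping[str, float] | None = None,
    ) -> tuple[str, float, dict[str, float]]:
        """Maximise one reaction's flux at steady state.

        ``fixed`` overrides bounds per reaction; ``minimum`` raises lower
        bounds.  Returns (status, optimum, fluxes) with status ``optimal``
        or ``infeasible``.
        """
        obj = objective or self.objective
        if obj is None or obj not in self.reactions:
            raise ValueError(f"objective reaction {obj!r} not in model")
        rids = sorted(self.reactions)
        idx = {rid: i for i, rid in enumerate(rids)}
        compounds = self.compounds
        cidx = {c: i for i, c in enumerate(compounds)}
        data, ri, ci = [], [], []
        for rid in rids:
            for c, v in self.reactions[rid].stoichiometry.items():
                ri.append(cidx[c])
                ci.append(idx[rid])
                data.append(float(v))
        a_eq = sparse.csr_matrix((data, (ri, ci)), shape=(len(compounds), len(rids)))
        bounds = []
        for rid in rids:
            r = self.reactions[rid]
            lb, ub = r.lb, r.ub
            if fixed and rid in fixed:
                lb, ub = fixed[rid]
            if minimum and rid in minimum:
                lb = max(lb, minimum[rid])
            bounds.append((lb, ub))
        c = np.zeros(len(rids))
        c[idx[obj]] = -1.0  # maximise
        res = linprog(c, A_eq=a_eq, b_eq=np.zeros(len(compounds)), bounds=bounds)
        if res.status == 2:
            return "infeasible", 0.0, {}
        if res.status != 0:
            raise RuntimeError(f"LP backend failure: {res.message}")
        fluxes = {rid: float(res.x[idx[rid]]) for rid in rids}
        return "optimal", float(-res.fun), fluxes


@dataclass(frozen=True)
class YieldResult:
    pathway_id: str
    pathway_length: int
    max_biomass: float
    max_target_flux: float
    yield_: float
    note: str = ""


def eco_mini_model(uptake: float = 10.0) -> FluxModel:
    """Toy chassis: glucose uptake, a 1:1 route to precursor A, a waste
    branch to B, and a biomass reaction consuming A."""
    m = FluxModel()
    m.add_exchange("glucose", lb=-uptake, ub=0.0)
    m.add_reaction(FluxReaction("R_ga", {"glucose": Fraction(-1), "A": Fraction(1)}))
    m.add_reaction(FluxReaction("R_gb", {"glucose": Fraction(-1), "B": Fraction(1)}))
    m.add_exchange("B")
    m.add_reaction(FluxReaction("R_biomass", {"A": Fraction(-1), "biomass": Fraction(1)}))
    m.add_exchange("biomass")
    m.objective = "R_biomass"
    return m


def chassis_for_scope(
    db: MetabolicDatabase, scope: ChassisScope, uptake: float = 10.0
) -> FluxModel:
    """Minimal flux chassis for a fixture scope: every native compound gets an
    uptake exchange; biomass consumes the alphabetically first native
    compound.  Adequate for before/after pathway-integration sanity checks."""
    if not scope.native_compounds:
        raise ValueError("scope has no native compounds")
    m = FluxModel()
    for c in sorted(scope.native_compounds):
        m.add_exchange(c, lb=-uptake, ub=0.0)
    first = sorted(scope.native_compounds)[0]
    m.add_reaction(FluxReaction("R_biomass", {first: Fraction(-1), "biomass": Fraction(1)}))
    m.add_exchange("biomass")
    m.objective = "R_biomass"
    return m


def integrate_pathway(
    model: FluxModel,
    pathway,
    db: MetabolicDatabase,
    target: str,
) -> FluxModel:
    """Return a copy of the model with the pathway's reactions and a target
    exchange appended; the original model is untouched.

    Pathway reactions are added irreversibly in their selected direction
    with bounds [0, DEFAULT_UB] and raw (not sign-binarised) stoichiometry.
    """
    var_ids = pathway.reactions if hasattr(pathway, "reactions") else tuple(pathway)
    out = model.copy()
    known = set(out.compounds) | set(db.compounds)
    for v in var_ids:
        rid = variable_reaction_id(v)
        if rid not in db.reactions:
            raise IntegrationError(f"pathway reaction {rid!r} absent from database")
        stoich = directed_stoichiometry(db.reactions[rid], variable_is_forward(v))
        missing = [c for c in stoich if c not in known]
        if missing:
            raise IntegrationError(
                f"pathway reaction {rid!r} references unknown compounds {missing}"
            )
        out.add_reaction(FluxReaction(v, dict(stoich)))
    if f"EX_{target}" not in out.reactions:
        out.add_exchange(target)
    return out


def remove_pathway(model: FluxModel, pathway, target: str) -> FluxModel:
    """Inverse of :func:`integrate_pathway` (structural restore)."""
    var_ids = pathway.reactions if hasattr(pathway, "reactions") else tuple(pathway)
    out = model.copy()
    for v in var_ids:
        out.reactions.pop(v, None)
    out.reactions.pop(f"EX_{target}", None)
    return out


def compute_yield(
    model: FluxModel,
    target: str,
    carbon_source: str,
    basis_uptake: float,
    *,
    biomass_fraction: float = 0.0,
    pathway_id: str = "",
    pathway_length: int = 0,
) -> YieldResult:
    """Two-LP theoretical yield.

    ``carbon_source`` is the carbon exchange reaction id.  LP 1 maximises
    the model objective (biomass); LP 2 fixes carbon uptake at
    ``basis_uptake``, floors biomass at ``biomass_fraction`` of LP 1's
    optimum and maximises the target exchange.  Yield is the LP 2 optimum
    divided by the basis (mol target per mol carbon source).
    """
    if basis_uptake <= 0:
        raise ValueError("basis_uptake must be > 0")
    if carbon_source not in model.reactions:
        raise ValueError(f"carbon source exchange {carbon_source!r} not in model")
    ex_target = f"EX_{target}"
    if ex_target not in model.reactions:
        raise ValueError(f"target exchange {ex_target!r} not in model (integrate first)")
    status1, biomass_opt, _ = model.optimize()
    if status1 != "optimal":
        return YieldResult(pathway_id, pathway_length, 0.0, 0.0, 0.0, "biomass LP infeasible")
    fixed = {carbon_source: (-basis_uptake, -basis_uptake)}
    minimum = (
        {model.objective: biomass_fraction * biomass_opt} if biomass_fraction > 0 else None
    )
    status2, target_opt, _ = model.optimize(ex_target, fixed=fixed, minimum=minimum)
    if status2 != "optimal":
        return YieldResult(
            pathway_id, pathway_length, biomass_opt, 0.0, 0.0, "target LP infeasible"
        )
    return YieldResult(
        pathway_id, pathway_length, biomass_opt, target_opt, target_opt / basis_uptake
    )


def rank_pathways(results: Iterable[YieldResult]) -> list[YieldResult]:
    """Descending yield; ties broken by shorter pathway, then id."""
    return sorted(
        results, key=lambda r: (-r.yield_, r.pathway_length, r.pathway_id)
    )


def to_cobra_model(model: FluxModel, name: str = "retroflux"):
    """Export to a cobra model (for independent FBA cross-checks)."""
    import cobra

    cm = cobra.Model(name)
    for rid, r in sorted(model.reactions.items()):
        rx = cobra.Reaction(rid)
        rx.lower_bound, rx.upper_bound = r.lb, r.ub
        cm.add_reactions([rx])
        rx.add_metabolites(
            {
                cobra.Metabolite(c) if c not in cm.metabolites else cm.metabolites.get_by_id(c): float(v)
                for c, v in r.stoichiometry.items()
            }
        )
    if model.objective:
        cm.objective = model.objective
    return cm
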