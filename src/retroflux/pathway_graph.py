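"""Bipartite compound/process dependency graph, pathway extraction and checks.

After enumeration, the union of selected reaction variables is backtracked
from the target compound into a directed bipartite graph: process nodes
(reaction variables) and compound nodes, with compound->process edges for
inputs and process->compound edges for outputs.  Individual pathways are the
minimal connected subgraphs in which every retained non-native compound node
keeps at least one producing process; native compounds are free leaves.

The module also provides the two pathway checks used across the package:

``is_acyclic_pathway``
    whether the selected reactions admit a topological production order
    starting from native compounds (rules out closed cycles that satisfy
    the counting balance without a real source);
``verify_pathway``
    sign-binarised counting feasibility, independent of the MILP solver:
    every non-native intermediate net-produced >= 0 and the target >= 1,
    optionally with help from native reactions that touch non-native
    compounds.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import networkx as nx

from .milp_core import (
    REVERSE_SUFFIX,
    directed_stoichiometry,
    variable_is_forward,
    variable_reaction_id,
)
from .netdb import ChassisScope, MetabolicDatabase, ReactionType

__all__ = [
    "DependencyGraph",
    "build_dependency_graph",
    "extract_feasible_subgraphs",
    "is_acyclic_pathway",
    "verify_pathway",
    "to_dot",
]

_NATIVE_HELP_GUARD = 12


def _var_ids(pathway) -> frozenset[str]:
    """Accept a Pathway record or a bare iterable of variable ids."""
    if hasattr(pathway, "reactions"):
        return frozenset(pathway.reactions)
    return frozenset(pathway)


def _var_stoich(var_id: str, db: MetabolicDatabase) -> dict:
    rid = variable_reaction_id(var_id)
    return directed_stoichiometry(db.reactions[rid], variable_is_forward(var_id))


class DependencyGraph(nx.DiGraph):
    """Directed bipartite graph; node attribute ``kind`` in {compound, process}."""

    root: str

    @property
    def compound_nodes(self) -> set[str]:
        return {n for n, d in self.nodes(data=True) if d["kind"] == "compound"}

    @property
    def process_nodes(self) -> set[str]:
        return {n for n, d in self.nodes(data=True) if d["kind"] == "process"}


def build_dependency_graph(
    union_vars: Iterable[str],
    target: str,
    db: MetabolicDatabase,
    scope: ChassisScope,
) -> DependencyGraph:
    """Backtrack from the target through the union of enumerated variables.

    Worklist in two alternating steps: attach the producers of the current
    compound as process nodes (removing them from the pending pool), then
    enqueue their non-native input compounds.  Native inputs become leaf
    compound nodes and are never expanded.
    """
    pool = set(union_vars)
    g = DependencyGraph()
    g.root = target
    g.add_node(target, kind="compound", native=scope.is_native_compound(target))
    queue = [target]
    seen_compounds = {target}
    while queue:
        cid = queue.pop(0)
        producers = sorted(
            v for v in pool if _var_stoich(v, db).get(cid, 0) > 0
        )
        for v in producers:
            pool.discard(v)
            stoich = _var_stoich(v, db)
            rxn = db.reactions[variable_reaction_id(v)]
            g.add_node(v, kind="process", rxn_type=rxn.rxn_type.value, enzyme=rxn.enzyme)
            for c, coef in stoich.items():
                if coef > 0:
                    g.add_node(
                        c, kind="compound", native=scope.is_native_compound(c)
                    )
                    g.add_edge(v, c)
                else:
                    native = scope.is_native_compound(c)
                    g.add_node(c, kind="compound", native=native)
                    g.add_edge(c, v)
                    if not native and c not in seen_compounds:
                        seen_compounds.add(c)
                        queue.append(c)
    if not any(True for _ in g.predecessors(target)):
        raise ValueError(
            f"target {target!r} has no producer among the supplied variables"
        )
    return g


def _subgraph_feasible(
    processes: frozenset[str],
    target: str,
    db: MetabolicDatabase,
    scope: ChassisScope,
) -> bool:
    """Proposition check: target retained, every needed non-native compound
    keeps a producer, and the retained processes are connected through their
    compounds."""
    if not processes:
        return False
    produced: dict[str, set[str]] = {}
    needed: set[str] = set()
    for v in processes:
        for c, coef in _var_stoich(v, db).items():
            if coef > 0:
                produced.setdefault(c, set()).add(v)
            elif not scope.is_native_compound(c):
                needed.add(c)
    if target not in produced:
        return False
    for c in needed:
        if not produced.get(c):
            return False
    # connectivity on the induced bipartite subgraph
    g = nx.Graph()
    for v in processes:
        g.add_node(("p", v))
        for c, coef in _var_stoich(v, db).items():
            g.add_node(("c", c))
            g.add_edge(("p", v), ("c", c))
    return nx.is_connected(g) if g.number_of_nodes() else False


def extract_feasible_subgraphs(
    g: DependencyGraph,
    db: MetabolicDatabase,
    scope: ChassisScope,
    *,
    require_acyclic: bool = True,
) -> list[frozenset[str]]:
    """All minimal process-node subsets that form feasible pathway subgraphs.

    A subset is kept when it satisfies the feasibility Proposition, no
    process can be dropped without breaking it, and (by default) it admits a
    topological production order.  Only non-native (E-block) processes count
    toward subset size; native weight-0 processes, if present in the graph,
    ride along for free.
    """
    target = g.root
    procs = sorted(g.process_nodes)
    nonnative_procs = [
        v for v in procs if variable_reaction_id(v) not in scope.native_reactions
    ]
    native_procs = frozenset(procs) - frozenset(nonnative_procs)
    results: list[frozenset[str]] = []
    for size in range(1, len(nonnative_procs) + 1):
        for combo in combinations(nonnative_procs, size):
            sel = frozenset(combo)
            if any(r < sel for r in results):
                continue  # superset of an already-minimal solution
            full = sel | native_procs
            if not _subgraph_feasible(full, target, db, scope):
                continue
            # minimality: no droppable process
            if any(
                _subgraph_feasible((sel - {v}) | native_procs, target, db, scope)
                for v in sel
            ):
                continue
            if require_acyclic and not is_acyclic_pathway(sel, db, scope):
                continue
            results.append(sel)
    return sorted(results, key=lambda s: (len(s), sorted(s)))


def is_acyclic_pathway(
    pathway, db: MetabolicDatabase, scope: ChassisScope
) -> bool:
    """True iff the selection admits a topological production order.

    Forward chaining from native availability: a reaction may fire once all
    its non-native substrates have been produced by an earlier reaction.
    The empty selection is trivially acyclic.
    """
    remaining = set(_var_ids(pathway))
    available = set(scope.native_compounds)
    progress = True
    while remaining and progress:
        progress = False
        for v in sorted(remaining):
            stoich = _var_stoich(v, db)
            if all(c in available for c, coef in stoich.items() if coef < 0):
                available.update(c for c, coef in stoich.items() if coef > 0)
                remaining.discard(v)
                progress = True
    return not remaining


def _relevant_native_vars(
    db: MetabolicDatabase, scope: ChassisScope
) -> list[str]:
    """Native-reaction variables that touch any non-native compound."""
    out = []
    for rid in sorted(scope.native_reactions & set(db.reactions)):
        r = db.reactions[rid]
        touches = any(
            not scope.is_native_compound(c) for c in r.stoichiometry
        )
        if touches:
            out.append(rid)
            if r.reversible:
                out.append(rid + REVERSE_SUFFIX)
    return out


def _counting_feasible(
    selection: frozenset[str],
    db: MetabolicDatabase,
    scope: ChassisScope,
    target: str,
) -> bool:
    balance: dict[str, int] = {}
    used_rxns: dict[str, str] = {}
    for v in selection:
        rid = variable_reaction_id(v)
        if rid in used_rxns and used_rxns[rid] != v:
            return False  # both directions of one reversible reaction
        used_rxns[rid] = v
        for c, coef in _var_stoich(v, db).items():
            if scope.is_native_compound(c):
                continue
            balance[c] = balance.get(c, 0) + (1 if coef > 0 else -1)
    if balance.get(target, 0) < 1:
        return False
    return all(v >= 0 for v in balance.values())


def verify_pathway(
    pathway,
    db: MetabolicDatabase,
    scope: ChassisScope,
    target: str,
) -> bool:
    """Independent counting-feasibility check for a candidate pathway.

    The pathway's variables are forced on; native reactions that touch
    non-native compounds may be enabled for free (all subsets tried, guarded
    to a small count).  An empty pathway verifies iff the target is native.
    """
    sel = _var_ids(pathway)
    if not sel:
        return scope.is_native_compound(target)
    helpers = _relevant_native_vars(db, scope)
    if len(helpers) > _NATIVE_HELP_GUARD:
        raise ValueError(
            f"too many native reactions touching non-native compounds "
            f"({len(helpers)} > {_NATIVE_HELP_GUARD}) for exhaustive verification"
        )
    for k in range(len(helpers) + 1):
        for extra in combinations(helpers, k):
            if _counting_feasible(sel | frozenset(extra), db, scope, target):
                return True
    return False


# ---------------------------------------------------------------------------
# DOT export
# ---------------------------------------------------------------------------

def to_dot(
    g: DependencyGraph,
    db: MetabolicDatabase,
    scope: ChassisScope,
    *,
    title: str = "pathways",
) -> str:
    """Graphviz DOT rendering: target red, native compounds magenta, chemical
    process steps dashed boxes, biological steps solid boxes."""
    lines = [f'digraph "{title}" {{', "  rankdir=LR;"]
    for n, d in sorted(g.nodes(data=True)):
        if d["kind"] == "compound":
            if n == g.root:
                color = "red"
            elif d.get("native"):
                color = "magenta"
            else:
                color = "lightgray"
            lines.append(
                f'  "{n}" [shape=ellipse, style=filled, fillcolor={color}];'
            )
        else:
            rxn = db.reactions[variable_reaction_id(n)]
            style = "dashed" if rxn.rxn_type is ReactionType.chemical else "solid"
            label = n if not rxn.enzyme else f"{n}\\n{rxn.enzyme}"
            lines.append(f'  "{n}" [shape=box, style={style}, label="{label}"];')
    for u, v in sorted(g.edges()):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"
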