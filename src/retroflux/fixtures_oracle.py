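"""Worked-example networks, a planted random-network generator, and an
exhaustive brute-force enumeration oracle.

The eight named fixtures encode published experimental/validation routes for
small industrially relevant targets (2-propanol, 1-butanol, 3-methylbutanol,
2-methylbutanal, isobutanol, pterostilbene, methyl acetate, benzene) as tiny
reaction networks over an *E. coli*-like chassis scope.  Intermediates the
route descriptions leave unnamed carry documented ``*_intermediate*``
placeholder ids; the tested surface is pathway counts and lengths, not
placeholder names.

The oracle enumerates every subset of non-native direction-split reaction
variables up to a length cap, keeps the counting-feasible, minimal (no
counting-feasible proper subset), topologically orderable sets, and groups
them by size.  It is deliberately naive — correctness over speed — and is
the independent cross-check for the MILP enumeration.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations

from .milp_core import REVERSE_SUFFIX, split_variables
from .netdb import (
    ChassisScope,
    Compound,
    MetabolicDatabase,
    Reaction,
    ReactionType,
)
from .pathway_graph import is_acyclic_pathway, verify_pathway

__all__ = [
    "FIXTURE_NAMES",
    "FixtureSpec",
    "PlantedNetwork",
    "NetworkKnobs",
    "GenerationError",
    "published_fixture",
    "random_network",
    "standard_benchmark_knobs",
    "brute_force_enumerate",
    "oracle_levels",
]

FIXTURE_NAMES = (
    "F-2PROH",
    "F-BUOH",
    "F-3MBOH",
    "F-MBUT",
    "F-IBOH",
    "F-PTSB",
    "F-MACET",
    "F-BENZ",
)

ORACLE_GUARD = 20


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """A worked network: database, chassis scope, target and expected truth.

    ``expected`` maps enumeration level to the set of pathway variable-sets
    at that level (empty set for a level known to be empty).  ``additions``
    holds user reactions that must be merged before the expectation applies
    (the 1-butanol case); ``premerge_infeasible`` marks that the unmerged
    network has no route.
    """

    name: str
    db: MetabolicDatabase
    scope: ChassisScope
    target: str
    expected: dict[int, frozenset[frozenset[str]]]
    additions: tuple[Reaction, ...] = ()
    premerge_infeasible: bool = False
    description: str = ""

    @property
    def expected_total(self) -> int:
        return sum(len(v) for v in self.expected.values())


def _bio(rid: str, sub: str, prod: str, enzyme: str | None = None) -> Reaction:
    return Reaction(
        rid,
        {sub: Fraction(-1), prod: Fraction(1)},
        rxn_type=ReactionType.biological,
        enzyme=enzyme,
    )


def _chem(rid: str, sub: str, prod: str) -> Reaction:
    return Reaction(
        rid, {sub: Fraction(-1), prod: Fraction(1)}, rxn_type=ReactionType.chemical
    )


def _mkdb(compound_ids, reactions) -> MetabolicDatabase:
    return MetabolicDatabase.from_lists(
        [Compound(c, c.replace("_", " ")) for c in compound_ids], reactions
    )


def _scope(native_compounds, native_reactions=(), organism="eco-k12") -> ChassisScope:
    return ChassisScope(organism, frozenset(native_compounds), frozenset(native_reactions))


def _fx_2propanol() -> FixtureSpec:
    compounds = [
        "acetoacetate", "farnesyl_diphosphate", "methylglyoxal",
        "acetone", "acetol", "fpp_acetone_intermediate", "2-propanol",
    ]
    rxns = [
        _bio("R_adc", "acetoacetate", "acetone", "4.1.1.4"),
        _bio("R_adh_2p", "acetone", "2-propanol", "1.1.1.80"),
        _bio("R_fpp_1", "farnesyl_diphosphate", "fpp_acetone_intermediate"),
        _bio("R_fpp_2", "fpp_acetone_intermediate", "acetone"),
        _bio("R_mgx_1", "methylglyoxal", "acetol"),
        _bio("R_mgx_2", "acetol", "acetone"),
    ]
    expected = {
        0: frozenset({frozenset({"R_adc", "R_adh_2p"})}),
        1: frozenset({
            frozenset({"R_fpp_1", "R_fpp_2", "R_adh_2p"}),
            frozenset({"R_mgx_1", "R_mgx_2", "R_adh_2p"}),
        }),
    }
    return FixtureSpec(
        "F-2PROH",
        _mkdb(compounds, rxns),
        _scope({"acetoacetate", "farnesyl_diphosphate", "methylglyoxal"}),
        "2-propanol",
        expected,
        description="2-propanol: 2-step optimum from acetoacetate; two 3-step "
        "alternatives from farnesyl diphosphate and methylglyoxal.",
    )


def _fx_butanol() -> FixtureSpec:
    compounds = ["2-ketobutyrate", "2-oxovalerate", "butanal", "butanol"]
    rxns = [
        _bio("R_kdc_butanal", "2-oxovalerate", "butanal", "4.1.1.72"),
        _bio("R_adh_buoh", "butanal", "butanol", "1.1.1.1"),
    ]
    additions = (
        _bio("R_leuABCD", "2-ketobutyrate", "2-oxovalerate", None),
    )
    expected = {
        0: frozenset({frozenset({"R_leuABCD", "R_kdc_butanal", "R_adh_buoh"})}),
    }
    return FixtureSpec(
        "F-BUOH",
        _mkdb(compounds, rxns),
        _scope({"2-ketobutyrate"}),
        "butanol",
        expected,
        additions=additions,
        premerge_infeasible=True,
        description="1-butanol: infeasible until the chain-elongation "
        "(leuABCD-style) 2-oxovalerate synthesis step is merged; then a "
        "unique 3-step route.",
    )


def _fx_3methylbutanol() -> FixtureSpec:
    compounds = ["2-keto-4-methylpentanoate", "3-methylbutanal", "3-methylbutanol"]
    rxns = [
        _bio("R_kdc_3mbal", "2-keto-4-methylpentanoate", "3-methylbutanal", "4.1.1.72"),
        _bio("R_adh_3mbol", "3-methylbutanal", "3-methylbutanol", "1.1.1.1"),
    ]
    expected = {0: frozenset({frozenset({"R_kdc_3mbal", "R_adh_3mbol"})})}
    return FixtureSpec(
        "F-3MBOH",
        _mkdb(compounds, rxns),
        _scope({"2-keto-4-methylpentanoate"}),
        "3-methylbutanol",
        expected,
        description="3-methylbutanol: unique 2-step route from the native "
        "keto acid 2-keto-4-methylpentanoate.",
    )


def _fx_2methylbutanal() -> FixtureSpec:
    compounds = [
        "2-methylbutanoyl_CoA", "isoleucine", "3-methyl-2-oxobutanoate",
        "3-methyl-2-oxopentanoate", "2-methylbutanal",
        "2-methylbutanoate", "2-methylbutanol",  # dead-end distractors
    ]
    rxns = [
        _bio("R_mbcoa_3m2op", "2-methylbutanoyl_CoA", "3-methyl-2-oxopentanoate"),
        _bio("R_ile_3m2op", "isoleucine", "3-methyl-2-oxopentanoate", "2.6.1.42"),
        _bio("R_3m2ob_3m2op", "3-methyl-2-oxobutanoate", "3-methyl-2-oxopentanoate"),
        _bio("R_3m2op_mbal", "3-methyl-2-oxopentanoate", "2-methylbutanal", "4.1.1.72"),
        _bio("R_mbal_mbac", "2-methylbutanal", "2-methylbutanoate"),
        _bio("R_mbac_mbol", "2-methylbutanoate", "2-methylbutanol"),
    ]
    shared = "R_3m2op_mbal"
    expected = {
        0: frozenset({
            frozenset({"R_mbcoa_3m2op", shared}),
            frozenset({"R_ile_3m2op", shared}),
            frozenset({"R_3m2ob_3m2op", shared}),
        }),
    }
    return FixtureSpec(
        "F-MBUT",
        _mkdb(compounds, rxns),
        _scope({"2-methylbutanoyl_CoA", "isoleucine", "3-methyl-2-oxobutanoate"}),
        "2-methylbutanal",
        expected,
        description="2-methylbutanal: three 2-step routes through the shared "
        "intermediate 3-methyl-2-oxopentanoate, from three native precursors; "
        "plus two dead-end distractor reactions.",
    )


def _fx_isobutanol() -> FixtureSpec:
    compounds = [
        "valine", "3-methyl-2-oxobutanoate", "isobutanal", "isobutanol",
        "isobutanoyl_CoA", "valine_isobutanal_intermediate",
    ]
    rxns = [
        _bio("R_kdc_ibal", "3-methyl-2-oxobutanoate", "isobutanal", "4.1.1.72"),
        _bio("R_adh_ibol", "isobutanal", "isobutanol", "1.1.1.1"),
        _bio("R_val_1", "valine", "valine_isobutanal_intermediate"),
        _bio("R_val_2", "valine_isobutanal_intermediate", "isobutanal"),
        _bio("R_coa_1", "3-methyl-2-oxobutanoate", "isobutanoyl_CoA"),
        _bio("R_coa_2", "isobutanoyl_CoA", "isobutanal", "1.2.1.10"),
    ]
    expected = {
        0: frozenset({frozenset({"R_kdc_ibal", "R_adh_ibol"})}),
        1: frozenset({
            frozenset({"R_val_1", "R_val_2", "R_adh_ibol"}),
            frozenset({"R_coa_1", "R_coa_2", "R_adh_ibol"}),
        }),
    }
    return FixtureSpec(
        "F-IBOH",
        _mkdb(compounds, rxns),
        _scope({"valine", "3-methyl-2-oxobutanoate"}),
        "isobutanol",
        expected,
        description="isobutanol: 2-step optimum from 3-methyl-2-oxobutanoate; "
        "3-step alternatives from valine (placeholder intermediate) and via "
        "isobutanoyl-CoA.",
    )


def _fx_pterostilbene() -> FixtureSpec:
    compounds = [
        "tyrosine", "phenylalanine", "coumarate", "cinnamate",
        "coumaroyl_CoA", "resveratrol", "pterostilbene",
    ]
    rxns = [
        _bio("R_tal", "tyrosine", "coumarate", "4.3.1.23"),
        _bio("R_pal", "phenylalanine", "cinnamate", "4.3.1.24"),
        _bio("R_c4h", "cinnamate", "coumarate", "1.14.14.91"),
        _bio("R_4cl", "coumarate", "coumaroyl_CoA", "6.2.1.12"),
        _bio("R_sts", "coumaroyl_CoA", "resveratrol", "2.3.1.95"),
        _bio("R_romt", "resveratrol", "pterostilbene", "2.1.1.240"),
    ]
    expected = {
        0: frozenset({frozenset({"R_tal", "R_4cl", "R_sts", "R_romt"})}),
        1: frozenset({
            frozenset({"R_pal", "R_c4h", "R_4cl", "R_sts", "R_romt"})
        }),
        2: frozenset(),
    }
    return FixtureSpec(
        "F-PTSB",
        _mkdb(compounds, rxns),
        _scope({"tyrosine", "phenylalanine"}),
        "pterostilbene",
        expected,
        description="pterostilbene: 4-step optimum from tyrosine, 5-step "
        "level-1 route from phenylalanine, no level-2 route.",
    )


def _fx_methyl_acetate() -> FixtureSpec:
    compounds = [
        "acetoacetate", "farnesyl_diphosphate", "methylglyoxal", "valine",
        "acetone", "acetol", "fpp_acetone_intermediate",
        "2-methylpropanal_oxime", "valine_acetone_intermediate_1",
        "valine_acetone_intermediate_2", "methyl_acetate",
    ]
    rxns = [
        _bio("R_adc", "acetoacetate", "acetone", "4.1.1.4"),
        _bio("R_bvmo", "acetone", "methyl_acetate", "1.14.13.x"),
        _bio("R_fpp_1", "farnesyl_diphosphate", "fpp_acetone_intermediate"),
        _bio("R_fpp_2", "fpp_acetone_intermediate", "acetone"),
        _bio("R_mgx_1", "methylglyoxal", "acetol"),
        _bio("R_mgx_2", "acetol", "acetone"),
        _bio("R_vox", "valine", "2-methylpropanal_oxime", "1.14.14.36"),
        _bio("R_vx_1", "2-methylpropanal_oxime", "valine_acetone_intermediate_1"),
        _bio("R_vx_2", "valine_acetone_intermediate_1", "valine_acetone_intermediate_2"),
        _bio("R_vx_3", "valine_acetone_intermediate_2", "acetone"),
    ]
    expected = {
        0: frozenset({frozenset({"R_adc", "R_bvmo"})}),
        1: frozenset({
            frozenset({"R_fpp_1", "R_fpp_2", "R_bvmo"}),
            frozenset({"R_mgx_1", "R_mgx_2", "R_bvmo"}),
        }),
        2: frozenset({
            frozenset({"R_vox", "R_vx_1", "R_vx_2", "R_vx_3", "R_bvmo"})
        }),
    }
    return FixtureSpec(
        "F-MACET",
        _mkdb(compounds, rxns),
        _scope({"acetoacetate", "farnesyl_diphosphate", "methylglyoxal", "valine"}),
        "methyl_acetate",
        expected,
        description="methyl acetate: acetone-to-ester final step shared by all "
        "routes; level 2 is a 5-step route via 2-methylpropanal-oxime from "
        "valine (levels skip length 4).",
    )


def _fx_benzene() -> FixtureSpec:
    compounds = ["4-aminobenzoate", "phenylamine", "benzene"]
    rxns = [
        _bio("R_abz_decarb", "4-aminobenzoate", "phenylamine", "4.1.1.24"),
        _chem("R_chem_deamination", "phenylamine", "benzene"),
    ]
    expected = {
        0: frozenset({frozenset({"R_abz_decarb", "R_chem_deamination"})})
    }
    return FixtureSpec(
        "F-BENZ",
        _mkdb(compounds, rxns),
        _scope({"4-aminobenzoate"}),
        "benzene",
        expected,
        description="benzene: hybrid route — enzymatic decarboxylation of "
        "native 4-aminobenzoate to phenylamine, then a chemical deamination.",
    )


_BUILDERS = {
    "F-2PROH": _fx_2propanol,
    "F-BUOH": _fx_butanol,
    "F-3MBOH": _fx_3methylbutanol,
    "F-MBUT": _fx_2methylbutanal,
    "F-IBOH": _fx_isobutanol,
    "F-PTSB": _fx_pterostilbene,
    "F-MACET": _fx_methyl_acetate,
    "F-BENZ": _fx_benzene,
}


def published_fixture(name: str) -> FixtureSpec:
    """Return one of the named worked-example networks."""
    try:
        return _BUILDERS[name]()
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}") from None


# ---------------------------------------------------------------------------
# Random planted networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkKnobs:
    """Generator knobs.  ``depth`` is the planted optimal length."""

    depth: int = 3
    n_optimal: int = 2
    n_suboptimal: int = 1
    suboptimal_extra: int = 1
    n_distractors: int = 3
    n_cycles: int = 0
    reversible_fraction: float = 0.0
    chemical_fraction: float = 0.0
    extra_native: int = 2

    def __post_init__(self) -> None:
        if self.depth < 1 or self.n_optimal < 1:
            raise ValueError("depth and n_optimal must be positive")
        if self.suboptimal_extra < 1 and self.n_suboptimal:
            raise ValueError("suboptimal_extra must be >= 1")


@dataclass(frozen=True)
class PlantedNetwork:
    db: MetabolicDatabase
    scope: ChassisScope
    target: str
    planted: dict[int, frozenset[frozenset[str]]]  # length -> pathway sets
    seed: int
    knobs: NetworkKnobs

    @property
    def optimal_length(self) -> int:
        return min(self.planted)


def _plant_chain(
    rng: random.Random,
    prefix: str,
    source: str,
    target: str,
    length: int,
    compounds: list[str],
    reactions: list[Reaction],
    knobs: NetworkKnobs,
) -> frozenset[str]:
    chain = [source]
    for j in range(length - 1):
        cid = f"{prefix}_i{j}"
        compounds.append(cid)
        chain.append(cid)
    chain.append(target)
    ids = []
    for j in range(length):
        rid = f"{prefix}_s{j}"
        rxn_type = (
            ReactionType.chemical
            if rng.random() < knobs.chemical_fraction
            else ReactionType.biological
        )
        reactions.append(
            Reaction(
                rid,
                {chain[j]: Fraction(-1), chain[j + 1]: Fraction(1)},
                rxn_type=rxn_type,
            )
        )
        ids.append(rid)
    return frozenset(ids)


def random_network(knobs: NetworkKnobs, seed: int, *, max_retries: int = 20) -> PlantedNetwork:
    """Generate a reproducible network with planted ground-truth pathways.

    Planted routes are disjoint linear chains from distinct native sources to
    the target, so level-0 truth is constructive.  Distractors only consume
    planted compounds into fresh dead ends (they can never create a shorter
    route); cycles are source-less two-cycles feeding the target, which are
    counting-feasible but admit no production order.  The planted truth is
    validated against the brute-force oracle post-hoc; a knob combination
    that cannot validate raises :class:`GenerationError`.
    """
    for attempt in range(max_retries):
        net = _generate_once(knobs, seed * 1000 + attempt, seed)
        groups = brute_force_enumerate(
            net.db, net.scope, net.target,
            max_len=max(net.planted) if net.planted else knobs.depth,
        )
        l0 = net.optimal_length
        ok = (
            groups
            and min(groups) == l0
            and frozenset(groups[l0]) == net.planted[l0]
            and all(
                s in set(groups.get(length, []))
                for length, sets in net.planted.items()
                for s in sets
            )
        )
        if ok:
            return net
    raise GenerationError(
        f"knobs {knobs} admit no valid planted network after {max_retries} retries"
    )


def _generate_once(knobs: NetworkKnobs, rng_seed: int, seed: int) -> PlantedNetwork:
    rng = random.Random(rng_seed)
    target = "target"
    n_sources = knobs.n_optimal + knobs.n_suboptimal
    natives = [f"native_{i}" for i in range(n_sources + knobs.extra_native)]
    compounds: list[str] = [target] + list(natives)
    reactions: list[Reaction] = []
    planted: dict[int, set[frozenset[str]]] = {}

    for i in range(knobs.n_optimal):
        s = _plant_chain(
            rng, f"opt{i}", natives[i], target, knobs.depth, compounds, reactions, knobs
        )
        planted.setdefault(knobs.depth, set()).add(s)
    sub_len = knobs.depth + knobs.suboptimal_extra
    for i in range(knobs.n_suboptimal):
        s = _plant_chain(
            rng, f"sub{i}", natives[knobs.n_optimal + i], target, sub_len,
            compounds, reactions, knobs,
        )
        planted.setdefault(sub_len, set()).add(s)

    # dead-end distractors: consume an existing compound, produce a fresh one
    nonsink = [c for c in compounds if c != target]
    for i in range(knobs.n_distractors):
        src = rng.choice(nonsink)
        dead = f"dead_{i}"
        compounds.append(dead)
        reversible = rng.random() < knobs.reversible_fraction
        reactions.append(
            Reaction(
                f"distr_{i}",
                {src: Fraction(-1), dead: Fraction(1)},
                reversible=reversible,
            )
        )

    # source-less cycles feeding the target: counting-feasible, unorderable
    for i in range(knobs.n_cycles):
        a, b = f"cycA_{i}", f"cycB_{i}"
        compounds.extend([a, b])
        reactions.append(Reaction(f"cyc_{i}_ab", {a: Fraction(-1), b: Fraction(1)}))
        reactions.append(
            Reaction(f"cyc_{i}_ba", {b: Fraction(-1), a: Fraction(1), target: Fraction(1)})
        )

    db = _mkdb(compounds, reactions)
    scope = _scope(set(natives), organism=f"planted-seed-{seed}")
    return PlantedNetwork(
        db, scope, target,
        {k: frozenset(v) for k, v in planted.items()},
        seed, knobs,
    )


def standard_benchmark_knobs(seed: int) -> NetworkKnobs:
    """Deterministic per-seed knob schedule for the oracle-agreement suite.

    Varies depth 1-4, route counts, distractors, cycles and reversibility
    across seeds while keeping every network at <= 15 non-native reactions.
    """
    rng = random.Random(seed ^ 0x5EED)
    depth = 1 + rng.randrange(4)
    n_optimal = 1 + rng.randrange(3)
    n_suboptimal = rng.randrange(3)
    extra = 1 + rng.randrange(2)
    n_cycles = rng.randrange(3)
    budget = 15 - (n_optimal * depth + n_suboptimal * (depth + extra) + 2 * n_cycles)
    while budget < 0:
        if n_suboptimal:
            n_suboptimal -= 1
        elif n_optimal > 1:
            n_optimal -= 1
        else:
            depth -= 1
        budget = 15 - (n_optimal * depth + n_suboptimal * (depth + extra) + 2 * n_cycles)
    n_distractors = rng.randrange(min(4, budget + 1)) if budget > 0 else 0
    return NetworkKnobs(
        depth=depth,
        n_optimal=n_optimal,
        n_suboptimal=n_suboptimal,
        suboptimal_extra=extra,
        n_distractors=n_distractors,
        n_cycles=n_cycles,
        reversible_fraction=0.3 if seed % 3 == 0 else 0.0,
        chemical_fraction=0.2 if seed % 4 == 0 else 0.0,
    )


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_enumerate(
    db: MetabolicDatabase,
    scope: ChassisScope,
    target: str,
    max_len: int = 10,
) -> dict[int, list[frozenset[str]]]:
    """Exhaustive enumeration of minimal acyclic feasible pathway sets.

    Enumerates all subsets of non-native direction-split variables of size
    <= ``max_len`` in ascending size, keeps those that are counting-feasible
    (per :func:`~retroflux.pathway_graph.verify_pathway`), have no
    counting-feasible proper subset, and admit a topological production
    order.  Returns ``{size: [variable sets]}`` sorted by size.
    """
    if scope.is_native_compound(target):
        return {0: [frozenset()]}
    nonnative_rxns = [r for r in db.reactions if not scope.is_native_reaction(r)]
    if len(nonnative_rxns) > ORACLE_GUARD:
        raise ValueError(
            f"oracle guard: {len(nonnative_rxns)} non-native reactions > {ORACLE_GUARD}"
        )
    variables = [v.var_id for v in split_variables(db, scope) if v.nonnative]
    feasible: list[frozenset[str]] = []
    groups: dict[int, list[frozenset[str]]] = {}
    for size in range(1, min(max_len, len(variables)) + 1):
        for combo in combinations(variables, size):
            sel = frozenset(combo)
            if _both_directions(sel):
                continue
            if not verify_pathway(sel, db, scope, target):
                continue
            minimal = not any(f < sel for f in feasible)
            feasible.append(sel)
            if minimal and is_acyclic_pathway(sel, db, scope):
                groups.setdefault(size, []).append(sel)
    return {k: sorted(groups[k], key=sorted) for k in sorted(groups)}


def _both_directions(sel: frozenset[str]) -> bool:
    return any(
        v.endswith(REVERSE_SUFFIX) and v[: -len(REVERSE_SUFFIX)] in sel for v in sel
    )


def oracle_levels(
    groups: dict[int, list[frozenset[str]]], k: int
) -> list[tuple[int | None, frozenset[frozenset[str]]]]:
    """First ``k+1`` oracle groups as (length, set-of-sets), padded with
    ``(None, {})`` once exhausted — the shape the enumeration reports."""
    out: list[tuple[int | None, frozenset[frozenset[str]]]] = []
    for size in sorted(groups):
        if len(out) > k:
            break
        out.append((size, frozenset(groups[size])))
    while len(out) <= k:
        out.append((None, frozenset()))
    return out
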