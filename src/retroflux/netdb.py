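"""Reaction/compound database and chassis scope: data model and I/O.

The database is a plain-text, tab-separated, versioned format (``.rfdb``)
holding compound records and reaction records.  Stoichiometric coefficients
are exact rationals (:class:`fractions.Fraction`); parsers accept decimals
and plain ratios (``2``, ``0.5``, ``3/2``) and normalise them.  A chassis
scope partitions the database into native and non-native compounds and
reactions for one organism; nativeness is declared, never inferred.
"""

from __future__ import annotations

import enum
import io
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Compound",
    "Reaction",
    "ReactionType",
    "MetabolicDatabase",
    "ChassisScope",
    "SchemaError",
    "IntegrityError",
    "MergeConflictError",
    "load_database",
    "save_database",
    "load_scope",
    "save_scope",
    "scope_from_sbml",
    "merge_user_reactions",
]

FORMAT_HEADER = "# retroflux database v1"
SCOPE_HEADER = "# retroflux scope v1"


class SchemaError(ValueError):
    """Raised when a database/scope file does not parse under the schema."""


class IntegrityError(ValueError):
    """Raised on referential-integrity violations (dangling ids, duplicates)."""


class MergeConflictError(IntegrityError):
    """Raised when merging a reaction id that exists with different content."""


class ReactionType(str, enum.Enum):
    biological = "biological"
    chemical = "chemical"


@dataclass(frozen=True)
class Compound:
    id: str
    name: str = ""
    formula: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise IntegrityError("compound id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A (possibly reversible) reaction with signed rational stoichiometry.

    ``stoichiometry`` maps compound id to a signed coefficient: negative for
    substrates, positive for products.  Zero coefficients are rejected, and a
    reaction must have at least one substrate and one product.
    """

    id: str
    stoichiometry: Mapping[str, Fraction]
    reversible: bool = False
    rxn_type: ReactionType = ReactionType.biological
    enzyme: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise IntegrityError("reaction id must be non-empty")
        coeffs = {c: Fraction(v) for c, v in self.stoichiometry.items()}
        if any(v == 0 for v in coeffs.values()):
            raise IntegrityError(f"reaction {self.id}: zero coefficient stored")
        if not any(v < 0 for v in coeffs.values()) or not any(v > 0 for v in coeffs.values()):
            raise IntegrityError(
                f"reaction {self.id}: needs at least one substrate and one product"
            )
        object.__setattr__(self, "stoichiometry", dict(sorted(coeffs.items())))
        object.__setattr__(self, "rxn_type", ReactionType(self.rxn_type))

    @property
    def substrates(self) -> tuple[str, ...]:
        return tuple(c for c, v in self.stoichiometry.items() if v < 0)

    @property
    def products(self) -> tuple[str, ...]:
        return tuple(c for c, v in self.stoichiometry.items() if v > 0)

    def equation(self) -> str:
        """Human/machine readable equation string, canonical ordering."""

        def side(items: Iterable[tuple[str, Fraction]]) -> str:
            return " + ".join(f"{_fmt_coeff(abs(v))} {c}" for c, v in items)

        subs = [(c, v) for c, v in self.stoichiometry.items() if v < 0]
        prods = [(c, v) for c, v in self.stoichiometry.items() if v > 0]
        arrow = "<=>" if self.reversible else "->"
        return f"{side(subs)} {arrow} {side(prods)}"


def _fmt_coeff(v: Fraction) -> str:
    return str(v.numerator) if v.denominator == 1 else f"{v.numerator}/{v.denominator}"


@dataclass(frozen=True)
class MetabolicDatabase:
    """Immutable collection of compounds and reactions with referential integrity."""

    compounds: dict[str, Compound]
    reactions: dict[str, Reaction]

    def __post_init__(self) -> None:
        object.__setattr__(self, "compounds", dict(sorted(self.compounds.items())))
        object.__setattr__(self, "reactions", dict(sorted(self.reactions.items())))
        self.validate()

    @classmethod
    def from_lists(
        cls, compounds: Iterable[Compound], reactions: Iterable[Reaction]
    ) -> "MetabolicDatabase":
        cmap: dict[str, Compound] = {}
        for c in compounds:
            if c.id in cmap:
                raise IntegrityError(f"duplicate compound id {c.id!r}")
            cmap[c.id] = c
        rmap: dict[str, Reaction] = {}
        for r in reactions:
            if r.id in rmap:
                raise IntegrityError(f"duplicate reaction id {r.id!r}")
            rmap[r.id] = r
        return cls(cmap, rmap)

    def validate(self) -> None:
        for r in self.reactions.values():
            for cid in r.stoichiometry:
                if cid not in self.compounds:
                    raise IntegrityError(
                        f"reaction {r.id} references unknown compound {cid!r}"
                    )

    def producers_of(self, compound_id: str) -> list[Reaction]:
        """Reactions with the compound on the product side (forward direction)."""
        return [r for r in self.reactions.values() if compound_id in r.products]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicDatabase):
            return NotImplemented
        return self.compounds == other.compounds and self.reactions == other.reactions


@dataclass(frozen=True)
class ChassisScope:
    """Declared partition of a database into native and non-native content.

    Nativeness is a property of the chassis organism, not of topology: a
    compound produced by a native reaction may still be declared non-native.
    """

    organism: str
    native_compounds: frozenset[str]
    native_reactions: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "native_compounds", frozenset(self.native_compounds))
        object.__setattr__(self, "native_reactions", frozenset(self.native_reactions))

    def check_against(self, db: MetabolicDatabase) -> None:
        bad_c = self.native_compounds - set(db.compounds)
        bad_r = self.native_reactions - set(db.reactions)
        if bad_c or bad_r:
            raise IntegrityError(
                f"scope for {self.organism}: unknown native ids "
                f"compounds={sorted(bad_c)} reactions={sorted(bad_r)}"
            )

    def is_native_compound(self, cid: str) -> bool:
        return cid in self.native_compounds

    def is_native_reaction(self, rid: str) -> bool:
        return rid in self.native_reactions


# ---------------------------------------------------------------------------
# Text format
# ---------------------------------------------------------------------------

def _parse_coeff(tok: str, where: str) -> Fraction:
    try:
        return Fraction(tok)
    except (ValueError, ZeroDivisionError) as exc:
        raise SchemaError(f"{where}: bad coefficient {tok!r}") from exc


def _parse_equation(eq: str, where: str) -> tuple[dict[str, Fraction], bool]:
    if "<=>" in eq:
        lhs, rhs = eq.split("<=>")
        reversible = True
    elif "->" in eq:
        lhs, rhs = eq.split("->")
        reversible = False
    else:
        raise SchemaError(f"{where}: equation missing '->' or '<=>': {eq!r}")
    stoich: dict[str, Fraction] = {}

    def add_side(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            raise SchemaError(f"{where}: empty reaction side in {eq!r}")
        for term in side.split(" + "):
            parts = term.strip().split()
            if len(parts) == 1:
                coeff, cid = Fraction(1), parts[0]
            elif len(parts) == 2:
                coeff, cid = _parse_coeff(parts[0], where), parts[1]
            else:
                raise SchemaError(f"{where}: bad term {term!r}")
            if cid in stoich:
                raise SchemaError(f"{where}: compound {cid!r} appears twice in equation")
            stoich[cid] = sign * coeff

    add_side(lhs, -1)
    add_side(rhs, +1)
    return stoich, reversible


def loads_database(text: str, name: str = "<string>") -> MetabolicDatabase:
    compounds: list[Compound] = []
    reactions: list[Reaction] = []
    section = None
    lines = text.splitlines()
    if not lines or lines[0].strip() != FORMAT_HEADER:
        raise SchemaError(f"{name}:1: missing header {FORMAT_HEADER!r}")
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        where = f"{name}:{lineno}"
        if line.strip() in ("[compounds]", "[reactions]"):
            section = line.strip()
            continue
        fields = line.split("\t")
        if section == "[compounds]":
            if not 1 <= len(fields) <= 3:
                raise SchemaError(f"{where}: compound record needs 1-3 fields")
            cid = fields[0].strip()
            cname = fields[1].strip() if len(fields) > 1 else ""
            formula = fields[2].strip() or None if len(fields) > 2 else None
            compounds.append(Compound(cid, cname, formula))
        elif section == "[reactions]":
            if len(fields) != 5:
                raise SchemaError(
                    f"{where}: reaction record needs 5 tab-separated fields "
                    "(id, type, enzyme, source, equation)"
                )
            rid, rtype, enzyme, source, eq = (f.strip() for f in fields)
            try:
                rxn_type = ReactionType(rtype)
            except ValueError:
                raise SchemaError(f"{where}: unknown reaction type {rtype!r}") from None
            stoich, reversible = _parse_equation(eq, where)
            try:
                reactions.append(
                    Reaction(
                        rid,
                        stoich,
                        reversible=reversible,
                        rxn_type=rxn_type,
                        enzyme=enzyme or None,
                        source=source or None,
                    )
                )
            except IntegrityError as exc:
                raise SchemaError(f"{where}: {exc}") from exc
        else:
            raise SchemaError(f"{where}: record outside any section")
    return MetabolicDatabase.from_lists(compounds, reactions)


def dumps_database(db: MetabolicDatabase) -> str:
    """Canonical serialization: sorted ids, fixed field order, tab-separated."""
    out = io.StringIO()
    out.write(FORMAT_HEADER + "\n")
    out.write("[compounds]\n")
    for c in db.compounds.values():
        out.write(f"{c.id}\t{c.name}\t{c.formula or ''}\n")
    out.write("[reactions]\n")
    for r in db.reactions.values():
        out.write(
            f"{r.id}\t{r.rxn_type.value}\t{r.enzyme or ''}\t{r.source or ''}\t{r.equation()}\n"
        )
    return out.getvalue()


def load_database(path: str | Path) -> MetabolicDatabase:
    p = Path(path)
    return loads_database(p.read_text(), name=str(p))


def save_database(db: MetabolicDatabase, path: str | Path) -> None:
    Path(path).write_text(dumps_database(db))


def loads_scope(text: str, name: str = "<string>") -> ChassisScope:
    lines = text.splitlines()
    if not lines or lines[0].strip() != SCOPE_HEADER:
        raise SchemaError(f"{name}:1: missing header {SCOPE_HEADER!r}")
    organism = ""
    native_c: set[str] = set()
    native_r: set[str] = set()
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        kind = parts[0]
        if kind == "organism" and len(parts) == 2:
            organism = parts[1]
        elif kind == "compound" and len(parts) == 2:
            native_c.add(parts[1])
        elif kind == "reaction" and len(parts) == 2:
            native_r.add(parts[1])
        else:
            raise SchemaError(f"{name}:{lineno}: bad scope record {line!r}")
    return ChassisScope(organism, frozenset(native_c), frozenset(native_r))


def dumps_scope(scope: ChassisScope) -> str:
    out = io.StringIO()
    out.write(SCOPE_HEADER + "\n")
    out.write(f"organism\t{scope.organism}\n")
    for cid in sorted(scope.native_compounds):
        out.write(f"compound\t{cid}\n")
    for rid in sorted(scope.native_reactions):
        out.write(f"reaction\t{rid}\n")
    return out.getvalue()


def load_scope(path: str | Path) -> ChassisScope:
    p = Path(path)
    return loads_scope(p.read_text(), name=str(p))


def save_scope(scope: ChassisScope, path: str | Path) -> None:
    Path(path).write_text(dumps_scope(scope))


# ---------------------------------------------------------------------------
# SBML chassis import
# ---------------------------------------------------------------------------

def scope_from_sbml(
    path: str | Path,
    *,
    id_map: Mapping[str, str] | None = None,
    include_boundary: bool = False,
    organism: str | None = None,
) -> tuple[ChassisScope, MetabolicDatabase]:
    """Derive a chassis scope (and database fragment) from an SBML model.

    Every model species becomes a native compound and every model reaction a
    native reaction.  ``id_map`` renames SBML ids to database ids; unmapped
    ids pass through with a warning.  Boundary-condition species are excluded
    from the native set unless ``include_boundary``.

    Exchange-style reactions (one-sided stoichiometry after boundary-species
    removal) are kept out of the returned database fragment — the pathway
    data model requires both a substrate and a product — but their ids still
    count as native reactions in the scope.
    """
    import libsbml

    doc = libsbml.readSBMLFromString(Path(path).read_text())
    if doc.getModel() is None or doc.getNumErrors() > 0 and any(
        doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
        for i in range(doc.getNumErrors())
    ):
        raise SchemaError(f"{path}: not a valid SBML document")
    model = doc.getModel()
    id_map = dict(id_map or {})
    seen_unmapped: set[str] = set()

    def mapped(sid: str) -> str:
        if sid in id_map:
            return id_map[sid]
        if id_map and sid not in seen_unmapped:
            seen_unmapped.add(sid)
            warnings.warn(f"SBML id {sid!r} not in id map; passing through")
        return sid

    boundary: set[str] = set()
    compounds: list[Compound] = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        cid = mapped(sp.getId())
        if sp.getBoundaryCondition():
            boundary.add(cid)
        compounds.append(Compound(cid, sp.getName() or cid))

    native_c = {c.id for c in compounds if include_boundary or c.id not in boundary}
    native_r: set[str] = set()
    reactions: list[Reaction] = []
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        rid = mapped(rx.getId())
        native_r.add(rid)
        stoich: dict[str, Fraction] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            cid = mapped(sr.getSpecies())
            coeff = Fraction(str(sr.getStoichiometry() or 1.0))
            stoich[cid] = stoich.get(cid, Fraction(0)) - coeff
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            cid = mapped(sr.getSpecies())
            coeff = Fraction(str(sr.getStoichiometry() or 1.0))
            stoich[cid] = stoich.get(cid, Fraction(0)) + coeff
        stoich = {c: v for c, v in stoich.items() if v != 0}
        has_sub = any(v < 0 for v in stoich.values())
        has_prod = any(v > 0 for v in stoich.values())
        if not (has_sub and has_prod):
            continue  # exchange/demand pseudo-reaction; scope keeps the id
        reactions.append(
            Reaction(rid, stoich, reversible=rx.getReversible(), source=model.getId() or None)
        )
    db = MetabolicDatabase.from_lists(compounds, reactions)
    scope = ChassisScope(organism or model.getId() or "sbml-model", native_c, native_r)
    return scope, db


# ---------------------------------------------------------------------------
# User additions
# ---------------------------------------------------------------------------

def merge_user_reactions(
    db: MetabolicDatabase,
    additions: Iterable[Reaction],
    new_compounds: Iterable[Compound] = (),
) -> MetabolicDatabase:
    """Union of the database with user-supplied reactions (and any new compounds).

    Adding a reaction identical to an existing one is a no-op; a colliding id
    with different content raises :class:`MergeConflictError` listing both
    stoichiometries.
    """
    compounds = dict(db.compounds)
    for c in new_compounds:
        if c.id in compounds and compounds[c.id] != c:
            raise MergeConflictError(f"compound {c.id!r} already present with different content")
        compounds[c.id] = c
    reactions = dict(db.reactions)
    for r in additions:
        if r.id in reactions:
            if reactions[r.id] == r:
                continue
            raise MergeConflictError(
                f"reaction id {r.id!r} conflict: existing {reactions[r.id].equation()!r} "
                f"vs addition {r.equation()!r}"
            )
        reactions[r.id] = r
    return MetabolicDatabase(compounds, reactions)
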