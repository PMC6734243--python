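"""Regenerate the shipped data files from the programmatic fixture builders.

Writes every worked-example network as a .rfdb/.scope pair plus a small
synthetic SBML chassis model (eco_mini.xml) into src/retroflux/data/.
The programmatic builders in retroflux.fixtures_oracle are the source of
truth; the shipped files exist for CLI/example use and round-trip tests.
"""

from __future__ import annotations

from pathlib import Path

import libsbml

from retroflux.fixtures_oracle import FIXTURE_NAMES, published_fixture
from retroflux.netdb import save_database, save_scope

DATA = Path(__file__).resolve().parents[1] / "src" / "retroflux" / "data"


def write_fixture_files() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    for name in FIXTURE_NAMES:
        fx = published_fixture(name)
        slug = name.lower().replace("-", "_")
        save_database(fx.db, DATA / f"{slug}.rfdb")
        save_scope(fx.scope, DATA / f"{slug}.scope")
        print(f"wrote {slug}.rfdb / {slug}.scope")


def write_eco_mini_sbml() -> None:
    """Synthetic toy chassis (glucose uptake, precursor A, waste branch B,
    biomass) as SBML Level 3 Version 1."""
    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId("eco_mini")
    model.setName("synthetic toy chassis")
    comp = model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)
    species = [
        ("glucose_e", True),  # boundary: external glucose
        ("glucose", False),
        ("A", False),
        ("B", False),
        ("biomass", False),
    ]
    for sid, boundary in species:
        s = model.createSpecies()
        s.setId(sid)
        s.setName(sid)
        s.setCompartment("c")
        s.setBoundaryCondition(boundary)
        s.setConstant(False)
        s.setHasOnlySubstanceUnits(False)
    reactions = [
        ("T_glc", [("glucose_e", 1.0)], [("glucose", 1.0)], False),
        ("R_ga", [("glucose", 1.0)], [("A", 1.0)], False),
        ("R_gb", [("glucose", 1.0)], [("B", 1.0)], False),
        ("R_biomass", [("A", 1.0)], [("biomass", 1.0)], False),
    ]
    for rid, subs, prods, rev in reactions:
        r = model.createReaction()
        r.setId(rid)
        r.setReversible(rev)
        r.setFast(False)
        for sid, coeff in subs:
            sr = r.createReactant()
            sr.setSpecies(sid)
            sr.setStoichiometry(coeff)
            sr.setConstant(True)
        for sid, coeff in prods:
            sr = r.createProduct()
            sr.setSpecies(sid)
            sr.setStoichiometry(coeff)
            sr.setConstant(True)
    out = DATA / "eco_mini.xml"
    libsbml.writeSBMLToFile(doc, str(out))
    print(f"wrote {out.name}")


if __name__ == "__main__":
    write_fixture_files()
    write_eco_mini_sbml()
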