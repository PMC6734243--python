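from __future__ import annotations

import importlib.resources as ir
from fractions import Fraction

import pytest

from retroflux.fixtures_oracle import FIXTURE_NAMES, published_fixture
from retroflux.netdb import Compound, MetabolicDatabase, Reaction, merge_user_reactions


@pytest.fixture(scope="session", params=FIXTURE_NAMES)
def fixture_spec(request):
    return published_fixture(request.param)


@pytest.fixture(scope="session")
def f2proh():
    return published_fixture("F-2PROH")


@pytest.fixture(scope="session")
def fmbut():
    return published_fixture("F-MBUT")


@pytest.fixture(scope="session")
def fptsb():
    return published_fixture("F-PTSB")


@pytest.fixture(scope="session")
def fbuoh_merged():
    """The 1-butanol network after merging the precursor-synthesis addition."""
    fx = published_fixture("F-BUOH")
    return fx, merge_user_reactions(fx.db, fx.additions)


@pytest.fixture(scope="session")
def data_dir():
    return ir.files("retroflux") / "data"


def linear_db(*edges: tuple[str, str]) -> MetabolicDatabase:
    """Tiny helper: unit-coefficient A->B reactions named R_<A>_<B>."""
    compounds = sorted({c for e in edges for c in e})
    rxns = [
        Reaction(f"R_{a}_{b}", {a: Fraction(-1), b: Fraction(1)}) for a, b in edges
    ]
    return MetabolicDatabase.from_lists([Compound(c) for c in compounds], rxns)
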