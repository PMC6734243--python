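"""Fixture encodings, the planted-network generator, and the brute-force oracle."""

from __future__ import annotations

import networkx as nx
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from retroflux.enumeration import enumerate_pathways
from retroflux.fixtures_oracle import (
    FIXTURE_NAMES,
    GenerationError,
    NetworkKnobs,
    brute_force_enumerate,
    oracle_levels,
    published_fixture,
    random_network,
)
from retroflux.milp_core import variable_is_forward, variable_reaction_id
from retroflux.netdb import ReactionType, merge_user_reactions
from retroflux.pathway_graph import verify_pathway


class TestPublishedFixtures:
    def test_unknown_name_rejected(self):
        with pytest.raises(KeyError):
            published_fixture("F-NOPE")

    def test_expected_pathways_all_verify(self, fixture_spec):
        db = fixture_spec.db
        if fixture_spec.additions:
            db = merge_user_reactions(db, fixture_spec.additions)
        for sets in fixture_spec.expected.values():
            for s in sets:
                assert verify_pathway(s, db, fixture_spec.scope, fixture_spec.target)

    def test_mbut_shape(self, fmbut):
        assert len(fmbut.db.compounds) == 7
        assert len(fmbut.db.reactions) == 6
        assert len(fmbut.scope.native_compounds) == 3

    def test_benzene_is_a_hybrid_route(self):
        fx = published_fixture("F-BENZ")
        types = {r.rxn_type for r in fx.db.reactions.values()}
        assert types == {ReactionType.biological, ReactionType.chemical}

    def test_2propanol_native_set(self, f2proh):
        assert f2proh.scope.native_compounds == {
            "acetoacetate", "farnesyl_diphosphate", "methylglyoxal",
        }


class TestRandomNetworks:
    def test_reproducible_from_seed(self):
        knobs = NetworkKnobs(depth=3, n_optimal=2, n_distractors=3, n_cycles=1)
        a, b = random_network(knobs, 42), random_network(knobs, 42)
        assert a.db == b.db and a.planted == b.planted

    def test_seed42_two_planted_optima_confirmed_by_oracle(self):
        net = random_network(NetworkKnobs(depth=3, n_optimal=2, n_suboptimal=0), 42)
        groups = brute_force_enumerate(net.db, net.scope, net.target, max_len=5)
        assert min(groups) == 3
        assert len(groups[3]) == 2
        assert frozenset(groups[3]) == net.planted[3]

    def test_depth_one_no_distractors_single_step(self):
        net = random_network(
            NetworkKnobs(depth=1, n_optimal=1, n_suboptimal=0, n_distractors=0), 1
        )
        groups = brute_force_enumerate(net.db, net.scope, net.target)
        assert list(groups) == [1]
        assert len(groups[1]) == 1

    def test_cycle_knob_creates_compound_cycles(self):
        net = random_network(NetworkKnobs(depth=2, n_optimal=1, n_cycles=2), 8)
        g = nx.DiGraph()
        for r in net.db.reactions.values():
            for s in r.substrates:
                for p in r.products:
                    g.add_edge(s, p)
        nonnative = set(net.db.compounds) - net.scope.native_compounds
        cycles = [
            c for c in nx.simple_cycles(g.subgraph(nonnative))
        ]
        assert len(cycles) >= 2

    def test_planted_sets_are_feasible_and_distinct(self):
        net = random_network(NetworkKnobs(depth=3, n_optimal=3, n_suboptimal=1), 5)
        flat = [s for sets in net.planted.values() for s in sets]
        assert len(flat) == len(set(flat)) == 4
        for s in flat:
            assert verify_pathway(s, net.db, net.scope, net.target)

    def test_impossible_knobs_raise_generation_error(self, monkeypatch):
        # force validation failure by planting two identical chains is not
        # possible via knobs; instead shrink retries and corrupt the oracle
        import retroflux.fixtures_oracle as fo

        monkeypatch.setattr(fo, "brute_force_enumerate", lambda *a, **k: {})
        with pytest.raises(GenerationError):
            fo.random_network(NetworkKnobs(depth=1, n_optimal=1), 1, max_retries=2)


class TestBruteForceOracle:
    def test_2propanol_groups(self, f2proh):
        groups = brute_force_enumerate(f2proh.db, f2proh.scope, f2proh.target, max_len=4)
        assert {k: len(v) for k, v in groups.items()} == {2: 1, 3: 2}

    def test_no_reactions_means_no_pathways(self, f2proh):
        from retroflux.netdb import MetabolicDatabase

        empty = MetabolicDatabase(f2proh.db.compounds, {})
        assert brute_force_enumerate(empty, f2proh.scope, f2proh.target) == {}

    def test_native_target_is_the_empty_pathway(self, f2proh):
        groups = brute_force_enumerate(f2proh.db, f2proh.scope, "acetoacetate")
        assert groups == {0: [frozenset()]}

    def test_guard_on_large_networks(self):
        net = random_network(NetworkKnobs(depth=3, n_optimal=2), 1)
        import retroflux.fixtures_oracle as fo

        big = NetworkKnobs(depth=4, n_optimal=3, n_suboptimal=3, n_distractors=0)
        netbig = fo._generate_once(big, 0, 0)
        assert len(netbig.db.reactions) > 20
        with pytest.raises(ValueError, match="guard"):
            brute_force_enumerate(netbig.db, netbig.scope, netbig.target)

    def test_reverse_variables_respect_direction_pairing(self):
        net = random_network(
            NetworkKnobs(depth=2, n_optimal=2, n_distractors=4, reversible_fraction=1.0),
            seed=6,
        )
        groups = brute_force_enumerate(net.db, net.scope, net.target, max_len=5)
        for sets in groups.values():
            for s in sets:
                rids = [variable_reaction_id(v) for v in s]
                assert len(rids) == len(set(rids))


@settings(
    max_examples=15,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
@given(
    seed=st.integers(min_value=0, max_value=10_000),
    depth=st.integers(min_value=1, max_value=3),
    n_optimal=st.integers(min_value=1, max_value=3),
    n_cycles=st.integers(min_value=0, max_value=1),
)
def test_property_solver_matches_oracle_on_random_networks(seed, depth, n_optimal, n_cycles):
    """The MILP enumeration and the exhaustive oracle agree on beta* and on
    the full level-0 pathway set for arbitrary small planted networks."""
    knobs = NetworkKnobs(
        depth=depth, n_optimal=n_optimal, n_suboptimal=1, n_distractors=2,
        n_cycles=n_cycles, reversible_fraction=0.25,
    )
    net = random_network(knobs, seed)
    state = enumerate_pathways(net.db, net.scope, net.target, k=1, max_len=depth + 2)
    groups = brute_force_enumerate(net.db, net.scope, net.target, max_len=depth + 2)
    got = [
        (state.level_objectives[l], frozenset(p.reaction_set for p in state.found[l]))
        for l in (0, 1)
    ]
    assert got == oracle_levels(groups, 1)
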