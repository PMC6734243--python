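"""All-optima penalty loop, sub-optimal levels, integer cuts, cycle handling."""

from __future__ import annotations

from fractions import Fraction

import pytest

from retroflux.enumeration import (
    enumerate_all_optimal,
    enumerate_pathways,
    enumerate_suboptimal,
)
from retroflux.fixtures_oracle import (
    NetworkKnobs,
    brute_force_enumerate,
    oracle_levels,
    published_fixture,
    random_network,
)
from retroflux.milp_core import build_system
from retroflux.netdb import ChassisScope, merge_user_reactions
from retroflux.pathway_graph import is_acyclic_pathway, verify_pathway
from conftest import linear_db


def level_sets(state, level):
    return frozenset(p.reaction_set for p in state.found[level])


class TestAllOptimal:
    def test_2methylbutanal_three_pathways_of_two_steps(self, fmbut):
        state = enumerate_all_optimal(build_system(fmbut.db, fmbut.scope, fmbut.target))
        assert state.beta_star == 2
        assert len(state.found[0]) == 3
        assert all(p.length == 2 for p in state.found[0])
        assert all("R_3m2op_mbal" in p.reaction_set for p in state.found[0])

    def test_single_pathway_network_takes_two_solves(self):
        fx = published_fixture("F-3MBOH")
        state = enumerate_all_optimal(build_system(fx.db, fx.scope, fx.target))
        assert len(state.found[0]) == 1
        assert state.solve_counts[0] == 2

    def test_penalty_arithmetic_at_beta_two(self, f2proh):
        """At beta*=2 the penalty weight is 5/4, a disjoint alternative costs
        2, a one-shared-variable alternative 9/4, and the loop terminates at
        the bound 5/2."""
        system = build_system(f2proh.db, f2proh.scope, f2proh.target)
        state = enumerate_all_optimal(system)
        assert state.beta_star == 2
        assert state.penalty_weight == Fraction(5, 4)
        assert state.termination_bound == Fraction(5, 2)
        assert state.terminal_objectives[0] >= Fraction(5, 2)

    def test_all_found_pathways_have_exact_optimal_length(self, fixture_spec):
        db = fixture_spec.db
        if fixture_spec.additions:
            db = merge_user_reactions(db, fixture_spec.additions)
        state = enumerate_all_optimal(
            build_system(db, fixture_spec.scope, fixture_spec.target)
        )
        assert all(p.length == state.beta_star for p in state.found[0])

    def test_termination_solve_budget(self, fixture_spec):
        """Level 0 takes at most |found| + 1 solves plus one per cyclic cut
        (each accepted solve yields a distinct pathway; solve_min_steps
        internally runs a fixed two-stage scheme, counted once)."""
        db = fixture_spec.db
        if fixture_spec.additions:
            db = merge_user_reactions(db, fixture_spec.additions)
        state = enumerate_all_optimal(
            build_system(db, fixture_spec.scope, fixture_spec.target)
        )
        assert state.solve_counts[0] <= len(state.found[0]) + 1 + len(state.cyclic_cuts)


class TestSubOptimal:
    def test_2propanol_k1_total_three(self, f2proh):
        state = enumerate_pathways(f2proh.db, f2proh.scope, f2proh.target, k=1)
        assert [len(lvl) for lvl in state.found] == [1, 2]
        assert level_sets(state, 0) == f2proh.expected[0]
        assert level_sets(state, 1) == f2proh.expected[1]

    def test_pterostilbene_second_suboptimal_level_is_empty(self, fptsb):
        state = enumerate_pathways(fptsb.db, fptsb.scope, fptsb.target, k=2)
        assert [len(lvl) for lvl in state.found] == [1, 1, 0]
        assert state.found[1][0].length == 5
        assert "R_pal" in state.found[1][0].reaction_set

    def test_methyl_acetate_levels_skip_length_four(self):
        fx = published_fixture("F-MACET")
        state = enumerate_pathways(fx.db, fx.scope, fx.target, k=2)
        assert state.level_objectives == [2, 3, 5]
        assert level_sets(state, 2) == fx.expected[2]

    def test_k_zero_is_a_no_op(self, f2proh):
        system = build_system(f2proh.db, f2proh.scope, f2proh.target)
        state = enumerate_all_optimal(system)
        before = [list(lvl) for lvl in state.found]
        enumerate_suboptimal(state, system, 0)
        assert [list(lvl) for lvl in state.found] == before

    def test_no_duplicate_pathways_across_levels(self, fixture_spec):
        db = fixture_spec.db
        if fixture_spec.additions:
            db = merge_user_reactions(db, fixture_spec.additions)
        state = enumerate_pathways(db, fixture_spec.scope, fixture_spec.target, k=2)
        sets = [p.reaction_set for lvl in state.found for p in lvl]
        assert len(sets) == len(set(sets))

    def test_level_lengths_strictly_increase(self, fixture_spec):
        db = fixture_spec.db
        if fixture_spec.additions:
            db = merge_user_reactions(db, fixture_spec.additions)
        state = enumerate_pathways(db, fixture_spec.scope, fixture_spec.target, k=2)
        lengths = [
            {p.length for p in lvl} for lvl in state.found if lvl
        ]
        for lo, hi in zip(lengths, lengths[1:]):
            assert max(lo) < min(hi)

    def test_butanol_infeasible_until_precursor_step_merged(self, fbuoh_merged):
        fx, merged = fbuoh_merged
        assert enumerate_pathways(fx.db, fx.scope, fx.target).beta_star is None
        state = enumerate_pathways(merged, fx.scope, fx.target)
        assert state.beta_star == 3
        assert level_sets(state, 0) == fx.expected[0]

    def test_native_target_yields_single_empty_pathway(self, f2proh):
        state = enumerate_pathways(f2proh.db, f2proh.scope, "acetoacetate", k=1)
        assert state.beta_star == 0
        assert state.found[0][0].length == 0
        assert state.found[1] == []


class TestCycleExclusion:
    @staticmethod
    def _cyclic_net(with_alternative: bool):
        """A -> B, B -> A + target (a source-less 2-cycle that satisfies the
        counting balance); optionally a disjoint acyclic 2-step route
        nsrc -> C -> target."""
        from fractions import Fraction as F

        from retroflux.netdb import Compound, MetabolicDatabase, Reaction

        compounds = [Compound(c) for c in ("A", "B", "C", "target", "nsrc")]
        rxns = [
            Reaction("R_A_B", {"A": F(-1), "B": F(1)}),
            Reaction("R_B_AT", {"B": F(-1), "A": F(1), "target": F(1)}),
        ]
        if with_alternative:
            rxns += [
                Reaction("R_nsrc_C", {"nsrc": F(-1), "C": F(1)}),
                Reaction("R_C_T", {"C": F(-1), "target": F(1)}),
            ]
        db = MetabolicDatabase.from_lists(compounds, rxns)
        scope = ChassisScope("toy", frozenset({"nsrc"}), frozenset())
        return db, scope

    def test_sourceless_cycle_is_cut_and_infeasible(self):
        db, scope = self._cyclic_net(with_alternative=False)
        system = build_system(db, scope, "target")
        state = enumerate_all_optimal(system)
        assert state.found[0] == []
        assert len(state.cyclic_cuts) == 1
        assert state.cyclic_cuts[0].variable_set == {"R_A_B", "R_B_AT"}

    def test_acyclic_route_found_after_cycle_cut(self):
        db, scope = self._cyclic_net(with_alternative=True)
        state = enumerate_all_optimal(build_system(db, scope, "target"))
        assert level_sets(state, 0) == frozenset(
            {frozenset({"R_nsrc_C", "R_C_T"})}
        )
        assert len(state.cyclic_cuts) == 1
        assert all(is_acyclic_pathway(p, db, scope) for p in state.found[0])
        # and the oracle concurs, including rejecting the cycle
        groups = brute_force_enumerate(db, scope, "target", max_len=4)
        assert oracle_levels(groups, 0) == [
            (state.level_objectives[0], level_sets(state, 0))
        ]

    def test_generated_cyclic_networks_match_oracle(self):
        for seed in (2, 9, 17):
            net = random_network(
                NetworkKnobs(depth=3, n_optimal=2, n_cycles=2, n_distractors=1),
                seed=seed,
            )
            state = enumerate_pathways(net.db, net.scope, net.target, k=1, max_len=6)
            groups = brute_force_enumerate(net.db, net.scope, net.target, max_len=6)
            got = [
                (state.level_objectives[l], level_sets(state, l)) for l in (0, 1)
            ]
            assert got == oracle_levels(groups, 1)
            assert state.cyclic_cuts  # the planted cycles actually surfaced
            for lvl in state.found:
                for p in lvl:
                    assert is_acyclic_pathway(p, net.db, net.scope)


class TestOracleAgreement:
    @pytest.mark.parametrize("seed", [1, 7, 13, 21, 34])
    @pytest.mark.parametrize("k", [0, 1, 2])
    def test_enumeration_matches_brute_force(self, seed, k):
        from retroflux.fixtures_oracle import standard_benchmark_knobs

        net = random_network(standard_benchmark_knobs(seed), seed)
        state = enumerate_pathways(net.db, net.scope, net.target, k=k, max_len=6)
        groups = brute_force_enumerate(net.db, net.scope, net.target, max_len=6)
        got = [
            (state.level_objectives[l], level_sets(state, l)) for l in range(k + 1)
        ]
        assert got == oracle_levels(groups, k)

    def test_every_reported_pathway_verifies(self, fixture_spec):
        db = fixture_spec.db
        if fixture_spec.additions:
            db = merge_user_reactions(db, fixture_spec.additions)
        state = enumerate_pathways(db, fixture_spec.scope, fixture_spec.target, k=2)
        for lvl in state.found:
            for p in lvl:
                assert verify_pathway(p, db, fixture_spec.scope, fixture_spec.target)
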