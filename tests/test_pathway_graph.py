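"""Dependency-graph backtracking, subgraph extraction, acyclicity, verification."""

from __future__ import annotations

from itertools import combinations

import pytest

from retroflux.enumeration import enumerate_pathways
from retroflux.fixtures_oracle import (
    NetworkKnobs,
    brute_force_enumerate,
    published_fixture,
    random_network,
    standard_benchmark_knobs,
)
from retroflux.milp_core import build_system
from retroflux.netdb import ChassisScope
from retroflux.pathway_graph import (
    build_dependency_graph,
    extract_feasible_subgraphs,
    is_acyclic_pathway,
    to_dot,
    verify_pathway,
)


class TestBuildGraph:
    def test_2propanol_graph_structure(self, f2proh):
        state = enumerate_pathways(f2proh.db, f2proh.scope, f2proh.target, k=1)
        g = build_dependency_graph(
            state.union_variables, f2proh.target, f2proh.db, f2proh.scope
        )
        assert len(g.process_nodes) == 6
        assert {"2-propanol", "acetone"} <= g.compound_nodes
        # native inputs are leaves: present, never expanded, no predecessors
        for leaf in ("acetoacetate", "farnesyl_diphosphate", "methylglyoxal"):
            assert leaf in g.compound_nodes
            assert not list(g.predecessors(leaf))
        assert g.root == "2-propanol"
        assert g.compound_nodes.isdisjoint(g.process_nodes)

    def test_single_step_pathway_graph(self):
        fx = published_fixture("F-3MBOH")
        state = enumerate_pathways(fx.db, fx.scope, fx.target)
        g = build_dependency_graph(state.union_variables, fx.target, fx.db, fx.scope)
        assert g.process_nodes == set(state.found[0][0].reactions)
        assert all(
            g.nodes[n]["kind"] == "compound" for n in g.nodes if n not in g.process_nodes
        )

    def test_no_producer_raises(self, f2proh):
        with pytest.raises(ValueError, match="no producer"):
            build_dependency_graph(frozenset(), f2proh.target, f2proh.db, f2proh.scope)

    def test_every_found_pathway_is_a_subgraph(self):
        net = random_network(standard_benchmark_knobs(7), 7)
        state = enumerate_pathways(net.db, net.scope, net.target, k=1, max_len=6)
        g = build_dependency_graph(
            state.union_variables, net.target, net.db, net.scope
        )
        for p in state.all_pathways:
            assert p.reaction_set <= g.process_nodes


class TestExtraction:
    def test_mbut_three_subgraphs_differ_in_one_process(self, fmbut):
        state = enumerate_pathways(fmbut.db, fmbut.scope, fmbut.target)
        g = build_dependency_graph(
            state.union_variables, fmbut.target, fmbut.db, fmbut.scope
        )
        subs = extract_feasible_subgraphs(g, fmbut.db, fmbut.scope)
        assert len(subs) == 3
        for a, b in combinations(subs, 2):
            assert len(a - b) == 1 and len(b - a) == 1

    def test_chain_graph_has_exactly_one_subgraph(self, fptsb):
        state = enumerate_pathways(fptsb.db, fptsb.scope, fptsb.target)
        g = build_dependency_graph(
            state.union_variables, fptsb.target, fptsb.db, fptsb.scope
        )
        subs = extract_feasible_subgraphs(g, fptsb.db, fptsb.scope)
        assert subs == [state.found[0][0].reaction_set]

    def test_extraction_agrees_with_enumeration_and_oracle(self):
        net = random_network(standard_benchmark_knobs(7), 7)
        state = enumerate_pathways(net.db, net.scope, net.target, k=2, max_len=6)
        g = build_dependency_graph(
            state.union_variables, net.target, net.db, net.scope
        )
        subs = set(extract_feasible_subgraphs(g, net.db, net.scope))
        enumerated = {p.reaction_set for p in state.all_pathways}
        # extraction explores only the enumerated union, so equality holds
        assert subs == enumerated
        oracle = brute_force_enumerate(net.db, net.scope, net.target, max_len=6)
        min_len = min(oracle)
        assert {s for s in subs if len(s) == min_len} == set(oracle[min_len])


class TestAcyclicity:
    def test_linear_route_is_acyclic(self, f2proh):
        assert is_acyclic_pathway({"R_adc", "R_adh_2p"}, f2proh.db, f2proh.scope)

    def test_sourceless_two_cycle_is_cyclic(self):
        from fractions import Fraction as F

        from retroflux.netdb import Compound, MetabolicDatabase, Reaction

        db = MetabolicDatabase.from_lists(
            [Compound("A"), Compound("B"), Compound("t")],
            [
                Reaction("R_ab", {"A": F(-1), "B": F(1)}),
                Reaction("R_ba_t", {"B": F(-1), "A": F(1), "t": F(1)}),
            ],
        )
        scope = ChassisScope("toy", frozenset(), frozenset())
        assert not is_acyclic_pathway({"R_ab", "R_ba_t"}, db, scope)

    def test_oracle_feasible_sets_are_orderable(self):
        net = random_network(NetworkKnobs(depth=3, n_optimal=2, n_cycles=1), seed=4)
        groups = brute_force_enumerate(net.db, net.scope, net.target, max_len=6)
        for sets in groups.values():
            for s in sets:
                assert is_acyclic_pathway(s, net.db, net.scope)


class TestVerifier:
    def test_found_pathways_verify_and_are_minimal(self, f2proh):
        state = enumerate_pathways(f2proh.db, f2proh.scope, f2proh.target, k=1)
        for p in state.all_pathways:
            assert verify_pathway(p, f2proh.db, f2proh.scope, f2proh.target)
            for v in p.reaction_set:
                assert not verify_pathway(
                    p.reaction_set - {v}, f2proh.db, f2proh.scope, f2proh.target
                )

    def test_empty_pathway_verifies_only_for_native_target(self, f2proh):
        assert verify_pathway(frozenset(), f2proh.db, f2proh.scope, "acetoacetate")
        assert not verify_pathway(frozenset(), f2proh.db, f2proh.scope, "2-propanol")


class TestDotExport:
    def test_benzene_chemical_step_styled_distinctly(self):
        fx = published_fixture("F-BENZ")
        state = enumerate_pathways(fx.db, fx.scope, fx.target)
        g = build_dependency_graph(state.union_variables, fx.target, fx.db, fx.scope)
        dot = to_dot(g, fx.db, fx.scope)
        assert '"benzene" [shape=ellipse, style=filled, fillcolor=red]' in dot
        assert 'fillcolor=magenta' in dot  # native 4-aminobenzoate
        assert 'style=dashed' in dot  # chemical step
        assert 'style=solid' in dot  # biological step
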