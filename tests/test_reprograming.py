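"""Reprogramming graphs and multi-phase environment strategies."""

import pytest

from logimc.arctl import Modal, alpha_environment, atom_pattern, sat_set
from logimc.dynamics import attractors, full_stg
from logimc.reprogram import (
    Strategy,
    StrategyPhase,
    build_graph,
    check_strategy,
    search_environments,
)
from logimc.stable import PhenotypePattern


@pytest.fixture
def toggle_graph(toggle_lts, toggle_patterns, toggle_envs):
    return build_graph(toggle_lts, toggle_patterns.values(), toggle_envs)


class TestBuildGraph:
    def test_toggle_graph_exact_arc_set(self, toggle_graph):
        assert toggle_graph.arcs == (
            ("PA", "e0", "PB"),
            ("PA", "e1", "PA"),
            ("PB", "e0", "PB"),
            ("PB", "e1", "PB"),
        )

    def test_no_arc_out_of_the_deadlocked_pattern(self, toggle_graph):
        assert all(
            not (c1 == "PB" and c2 == "PA") for c1, _, c2 in toggle_graph.arcs
        )

    def test_single_pattern_yields_only_self_arcs(
        self, toggle_lts, toggle_patterns, toggle_envs
    ):
        graph = build_graph(
            toggle_lts, [toggle_patterns["PB"]], toggle_envs
        )
        assert all(c1 == c2 == "PB" for c1, _, c2 in graph.arcs)

    def test_unmatched_pattern_kept_as_isolated_node(
        self, toggle_lts, toggle_patterns, toggle_envs
    ):
        phantom = PhenotypePattern("ghost", {"A": 2})
        graph = build_graph(
            toggle_lts,
            list(toggle_patterns.values()) + [phantom],
            toggle_envs,
        )
        assert "ghost" in graph.nodes
        assert "ghost" in graph.empty_patterns
        assert all("ghost" not in (c1, c2) for c1, _, c2 in graph.arcs)

    def test_self_arc_iff_every_state_stays_in_pattern(
        self, toggle_lts, toggle_patterns, toggle_envs
    ):
        for name, pattern in toggle_patterns.items():
            goal = atom_pattern(pattern.constraints)
            for env_name, env in toggle_envs.items():
                alpha = alpha_environment(env)
                aag = sat_set(toggle_lts, Modal("AAG", alpha, goal))
                members = sat_set(toggle_lts, goal)
                expected = members <= aag
                graph = build_graph(
                    toggle_lts, toggle_patterns.values(), toggle_envs
                )
                assert ((name, env_name, name) in graph.arcs) == expected

    def test_invariant_under_declaration_order(
        self, toggle_lts, toggle_patterns, toggle_envs
    ):
        forward = build_graph(toggle_lts, toggle_patterns.values(), toggle_envs)
        backward = build_graph(
            toggle_lts,
            list(toggle_patterns.values())[::-1],
            dict(reversed(list(toggle_envs.items()))),
        )
        assert forward.arcs == backward.arcs

    def test_single_environment_matches_explicit_attractor_reachability(
        self, toggle, toggle_lts, toggle_patterns
    ):
        # under one fixed environment the arc property degenerates to
        # "every c1-state reaches a stable c2-attractor" in the plain STG
        graph = build_graph(
            toggle_lts, toggle_patterns.values(), {"e1": {"I": 1}}
        )
        stg = full_stg(toggle, {"I": 1})
        stable = {
            next(iter(a.states))
            for a in attractors(stg)
            if a.kind == "stable_state"
        }
        import networkx as nx

        for c1, p1 in toggle_patterns.items():
            init = [
                s
                for s in stg.states
                if p1.matches(dict(zip(stg.names, s)))
            ]
            for c2, p2 in toggle_patterns.items():
                goals = {
                    s for s in stable if p2.matches(dict(zip(stg.names, s)))
                }
                reach_ok = all(
                    any(
                        g == s or nx.has_path(stg.graph, s, g)
                        for g in goals
                    )
                    for s in init
                )
                assert (
                    (c1, "e1", c2) in graph.arcs
                ) == reach_ok

    def test_degree_helpers(self, toggle_graph):
        assert toggle_graph.in_degree("PB") == 1  # from PA only (non-self)
        assert toggle_graph.out_degree("PB") == 0
        assert toggle_graph.in_degree("PB", count_self=True) == 2


class TestStrategies:
    def test_single_phase_strategy_equals_graph_arc(self, toggle_lts, toggle_patterns):
        strategy = Strategy(
            (StrategyPhase({"I": 0}, dict(toggle_patterns["PB"].constraints)),)
        )
        result, witnesses = check_strategy(
            toggle_lts, toggle_patterns["PA"], strategy
        )
        assert result.holds
        assert len(witnesses) == 1

    def test_two_phase_strategy_through_intermediate(self, toggle_lts, toggle_patterns):
        strategy = Strategy(
            (
                StrategyPhase({"I": 0}, None),
                StrategyPhase({"I": 0}, dict(toggle_patterns["PB"].constraints)),
            )
        )
        result, _ = check_strategy(toggle_lts, toggle_patterns["PA"], strategy)
        assert result.holds

    def test_pb_cannot_be_reprogrammed_to_pa(self, toggle_lts, toggle_patterns):
        strategy = Strategy(
            (
                StrategyPhase({"I": 1}, None),
                StrategyPhase({"I": 0}, dict(toggle_patterns["PA"].constraints)),
            )
        )
        result, _ = check_strategy(toggle_lts, toggle_patterns["PB"], strategy)
        assert not result.holds

    def test_final_phase_needs_a_target(self):
        with pytest.raises(ValueError, match="final phase"):
            from logimc.reprogram import compile_strategy

            compile_strategy(Strategy((StrategyPhase({"I": 0}, None),)))


class TestSearchEnvironments:
    def test_one_phase_search_finds_exactly_i0(self, toggle_lts, toggle_patterns):
        found = search_environments(
            toggle_lts, toggle_patterns["PA"], toggle_patterns["PB"], ["I"], 1
        )
        assert [dict(s.phases[0].environment) for s in found] == [{"I": 0}]

    def test_unreachable_target_short_circuits(self, toggle_lts, toggle_patterns):
        found = search_environments(
            toggle_lts, toggle_patterns["PB"], toggle_patterns["PA"], ["I"], 2
        )
        assert found == []

    def test_self_target_trivially_satisfied_where_stable(
        self, toggle_lts, toggle_patterns
    ):
        found = search_environments(
            toggle_lts, toggle_patterns["PB"], toggle_patterns["PB"], ["I"], 1
        )
        assert len(found) == 2  # PB is stable under both input values

    def test_one_phase_search_agrees_with_graph(
        self, toggle_lts, toggle_patterns, toggle_envs, toggle_graph
    ):
        for c1 in toggle_patterns:
            for c2 in toggle_patterns:
                found = search_environments(
                    toggle_lts, toggle_patterns[c1], toggle_patterns[c2], ["I"], 1
                )
                envs = {
                    "e0" if s.phases[0].environment == {"I": 0} else "e1"
                    for s in found
                }
                from_graph = {
                    env for a, env, b in toggle_graph.arcs if a == c1 and b == c2
                }
                assert envs == from_graph

    def test_enumeration_guard(self, toggle_lts, toggle_patterns):
        with pytest.raises(RuntimeError, match="guard"):
            search_environments(
                toggle_lts,
                toggle_patterns["PA"],
                toggle_patterns["PB"],
                ["I"],
                2,
                guard=1,
            )

    def test_invalid_phase_count(self, toggle_lts, toggle_patterns):
        with pytest.raises(ValueError, match="max_phases"):
            search_environments(
                toggle_lts, toggle_patterns["PA"], toggle_patterns["PB"], ["I"], 3
            )


class TestExports:
    def test_dot_has_one_edge_per_arc(self, toggle_graph):
        dot = toggle_graph.to_dot()
        assert dot.count("->") == 4
        assert dot.count('"PA"') >= 2

    def test_dot_can_hide_self_arcs(self, toggle_graph):
        dot = toggle_graph.to_dot(include_self_arcs=False)
        assert dot.count("->") == 1  # only PA -> PB survives

    def test_json_round_trips_arcs(self, toggle_graph):
        import json

        payload = json.loads(toggle_graph.to_json())
        assert len(payload["arcs"]) == 4
        agg = {
            (row["from"], row["to"]): row["environments"]
            for row in payload["aggregated"]
        }
        assert agg[("PB", "PB")] == ["e0", "e1"]
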