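"""Model definition, validation, perturbations, and functionality analysis."""

import itertools

import pytest

from logimc import exhaustive, fixtures
from logimc.model import (
    ACTIVATION,
    INHIBITION,
    NONE,
    Component,
    Interaction,
    LogicalModel,
    LogicalRule,
    Perturbation,
    apply_perturbation,
    circuit_functionality,
    fix_inputs,
    interaction_functionality,
    regulatory_circuits,
    validate_model,
)


class TestValidation:
    def test_well_formed_fixture_has_no_errors(self, toggle):
        report = validate_model(toggle)
        assert report.errors == []
        assert report.ok

    def test_threshold_exceeding_source_max_is_an_error(self, toggle):
        bad = toggle.replace(
            interactions=list(toggle.interactions) + [Interaction("B", "A", 2)]
        )
        report = validate_model(bad)
        assert any("threshold exceeds source max" in e for e in report.errors)

    def test_rule_using_undeclared_regulator_is_an_error(self, toggle):
        maxes = {"I": 1, "B": 1, "C": 1}
        rules = dict(toggle.rules)
        rules["A"] = LogicalRule.from_function(
            "A", ("I", "B", "C"), maxes, lambda s: int(s["I"] and not s["B"])
        )
        bad = LogicalModel(
            toggle.components, rules.values(), toggle.interactions
        )
        report = validate_model(bad)
        assert any("non-regulator" in e for e in report.errors)

    def test_duplicate_names_and_missing_rules_reported(self):
        model = LogicalModel(
            [Component("A"), Component("A")],
            [LogicalRule.constant("A", 0)],
            interactions=(),
        )
        report = validate_model(model)
        assert any("duplicate" in e for e in report.errors)

    def test_out_of_range_rule_output_is_an_error(self):
        model = LogicalModel(
            [Component("A", max_level=1)],
            [LogicalRule.constant("A", 2)],
            interactions=(),
        )
        report = validate_model(model)
        assert any("out-of-range" in e for e in report.errors)

    def test_non_functional_declared_interaction_warns(self, toggle):
        # declare an extra A->A edge the rule never uses
        bad = toggle.replace(
            interactions=list(toggle.interactions) + [Interaction("A", "A", 1)]
        )
        report = validate_model(bad)
        assert report.ok
        assert any("not functional" in w for w in report.warnings)


class TestPerturbations:
    def test_knock_out_b_leaves_input_tracking_stable_states(self, toggle):
        perturbed = apply_perturbation(toggle, Perturbation.knock_out("B"))
        # (I, A, B) order; A follows I once B is silenced
        assert exhaustive.stable_full_states(perturbed) == {(0, 0, 0), (1, 1, 0)}
        # original untouched
        assert exhaustive.stable_full_states(toggle) == {
            (0, 0, 1),
            (1, 0, 1),
            (1, 1, 0),
        }

    def test_ectopic_is_a_constant_rule(self, toggle):
        perturbed = apply_perturbation(toggle, Perturbation.ectopic("A", 1))
        assert perturbed.rules["A"] == LogicalRule.constant("A", 1)

    def test_edge_suppression_clamps_source_below_threshold(self, toggle):
        edge = toggle.interaction("B", "A")
        perturbed = apply_perturbation(toggle, Perturbation.edge_suppression(edge))
        rule = perturbed.rules["A"]
        for i, b in itertools.product((0, 1), repeat=2):
            assert rule({"I": i, "B": b}) == i  # K_A reduces to [I=1]

    @pytest.mark.parametrize(
        "perturbation",
        [Perturbation.knock_out("B"), Perturbation.ectopic("A", 1)],
        ids=["knock_out", "ectopic"],
    )
    def test_knock_out_and_ectopic_are_idempotent(self, toggle, perturbation):
        once = apply_perturbation(toggle, perturbation)
        twice = apply_perturbation(once, perturbation)
        assert once.rules == twice.rules

    def test_conflicting_perturbations_rejected(self, toggle):
        with pytest.raises(ValueError, match="conflicting"):
            apply_perturbation(
                toggle,
                [Perturbation.knock_out("A"), Perturbation.ectopic("A", 1)],
            )

    def test_unknown_target_rejected(self, toggle):
        with pytest.raises(KeyError):
            apply_perturbation(toggle, Perturbation.knock_out("Z"))

    def test_combined_perturbations_apply_independently(self, toggle):
        perturbed = apply_perturbation(
            toggle,
            [Perturbation.knock_out("B"), Perturbation.ectopic("A", 1)],
        )
        assert perturbed.rules["A"] == LogicalRule.constant("A", 1)
        assert perturbed.rules["B"] == LogicalRule.constant("B", 0)


class TestInteractionFunctionality:
    def test_toggle_b_inhibits_a_in_context_i1(self, toggle):
        report = interaction_functionality(toggle, toggle.interaction("B", "A"))
        assert report.functional
        assert report.derived_sign == INHIBITION
        assert report.context == ({"I": 1},)

    def test_toggle_i_activates_a_in_context_b0(self, toggle):
        report = interaction_functionality(toggle, toggle.interaction("I", "A"))
        assert report.functional
        assert report.derived_sign == ACTIVATION
        assert report.context == ({"B": 0},)

    def test_unused_regulator_is_not_functional(self, toggle):
        report = interaction_functionality(toggle, Interaction("A", "A", 1))
        assert not report.functional
        assert report.derived_sign == NONE
        assert report.context == ()

    def test_functional_iff_witnessing_state_pair_exists(self):
        # exhaustive cross-check of the threshold comparison on small models
        for seed in range(20):
            model = fixtures.random_model(3, 1, 2, seed=seed)
            for edge in model.interactions:
                report = interaction_functionality(model, edge)
                rule = model.rules[edge.target]
                witness = False
                others = [r for r in rule.regulators if r != edge.source]
                maxes = model.max_levels
                for combo in itertools.product(
                    *(range(maxes[r] + 1) for r in others)
                ):
                    env = dict(zip(others, combo))
                    env[edge.source] = edge.threshold
                    hi = rule(env)
                    env[edge.source] = edge.threshold - 1
                    if rule(env) != hi:
                        witness = True
                        break
                assert report.functional == witness

    def test_derived_sign_matches_declared_sign_on_fixtures(self, toggle):
        for edge in toggle.interactions:
            report = interaction_functionality(toggle, edge)
            assert report.derived_sign == edge.declared_sign


class TestCircuitFunctionality:
    def test_toggle_mutual_inhibition_is_positive_under_i1(self, toggle):
        circuit = [toggle.interaction("A", "B"), toggle.interaction("B", "A")]
        sign, context = circuit_functionality(toggle, circuit)
        assert sign == "positive"
        assert context == ({"I": 1},)

    def test_self_activator_is_positive_with_empty_constraint(self):
        model = fixtures.self_activator()
        sign, context = circuit_functionality(model, [model.interaction("C", "C")])
        assert sign == "positive"
        assert context == ({},)  # functional with no external condition

    def test_input_restriction_empties_the_context(self, toggle):
        restricted = fix_inputs(toggle, {"I": 0})
        circuit = [Interaction("A", "B", 1), Interaction("B", "A", 1)]
        _, context = circuit_functionality(restricted, circuit)
        assert context == ()

    def test_non_cycle_rejected(self, toggle):
        with pytest.raises(ValueError, match="elementary cycle"):
            circuit_functionality(toggle, [toggle.interaction("A", "B")])

    def test_circuit_enumeration_finds_the_toggle_loop(self, toggle):
        circuits = regulatory_circuits(toggle)
        assert [
            tuple((e.source, e.target) for e in c) for c in circuits
        ] == [(("A", "B"), ("B", "A"))]

    def test_nonfunctional_circuit_edge_suppression_changes_nothing(self, toggle):
        # with I fixed at 0 the mutual-inhibition circuit is non-functional:
        # suppressing one of its edges must not change the stable states
        restricted = fix_inputs(toggle, {"I": 0})
        before = exhaustive.stable_full_states(restricted)
        suppressed = apply_perturbation(
            restricted,
            Perturbation.edge_suppression(restricted.interaction("A", "B")),
        )
        assert exhaustive.stable_full_states(suppressed) == before


class TestFixInputs:
    def test_fixing_an_input_partially_evaluates_rules(self, toggle):
        restricted = fix_inputs(toggle, {"I": 1})
        assert restricted.input_names == ()
        assert restricted.rules["A"].regulators == ("B",)
        assert restricted.rules["A"]({"B": 0}) == 1

    def test_fixing_a_non_input_is_rejected(self, toggle):
        with pytest.raises(ValueError, match="not an input"):
            fix_inputs(toggle, {"A": 1})
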