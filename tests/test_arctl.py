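"""Input-labeled transition systems and ARCTL fixpoint semantics."""

import pytest
from hypothesis import given, settings, strategies as st

from conftest import battery_models
from logimc import exhaustive, fixtures
from logimc.arctl import (
    AAtom,
    ANot,
    ATrue,
    And,
    Atom,
    FormulaTypeError,
    Modal,
    Not,
    TrueF,
    VacuousPropertyError,
    atom_pattern,
    build_lts,
    check,
    sat_set,
)
from logimc.dynamics import StateCapExceeded, full_stg


class TestBuildLts:
    def test_toggle_labels(self, toggle_lts):
        labels = {
            edge: sorted(vals) for edge, vals in sorted(toggle_lts.edges.items())
        }
        assert labels == {
            ((0, 0), (0, 1)): [(0,), (1,)],  # both input values enable it
            ((0, 0), (1, 0)): [(1,)],
            ((1, 0), (0, 0)): [(0,)],
            ((1, 1), (0, 1)): [(0,), (1,)],
            ((1, 1), (1, 0)): [(0,), (1,)],
        }
        assert len(toggle_lts.states) == 4

    def test_inputless_model_labels_are_all_true(self, negative_circuit):
        lts = build_lts(negative_circuit)
        assert all(label == frozenset({()}) for label in lts.edges.values())
        # degenerate labeling: the LTS is the ordinary STG
        stg = full_stg(negative_circuit, {})
        assert set(lts.edges) == set(stg.graph.edges)

    def test_step_chain_is_labeled_by_input_direction(self, step):
        lts = build_lts(step)
        up = {e for e, v in lts.edges.items() if v == frozenset({(1,)})}
        down = {e for e, v in lts.edges.items() if v == frozenset({(0,)})}
        assert up == {((0,), (1,)), ((1,), (2,))}
        assert down == {((2,), (1,)), ((1,), (0,))}

    def test_state_cap_guard(self, toggle):
        with pytest.raises(StateCapExceeded):
            build_lts(toggle, state_cap=2)


class TestSatSet:
    def test_eaf_backward_reachability_under_i0(self, toggle_lts):
        got = sat_set(toggle_lts, Modal("EAF", AAtom("I", "=", 0), Atom("B", "=", 1)))
        assert got == set(toggle_lts.states)

    def test_aag_holds_at_deadlocked_satisfying_state(self, toggle_lts):
        got = sat_set(toggle_lts, Modal("AAG", AAtom("I", "=", 0), Atom("A", "=", 0)))
        assert (0, 1) in got

    def test_eaf_true_is_everything(self, toggle_lts):
        got = sat_set(toggle_lts, Modal("EAF", ATrue(), TrueF()))
        assert got == set(toggle_lts.states)

    def test_zero_length_paths_count_for_eaf(self, toggle_lts):
        phi = Atom("A", "=", 1)
        assert sat_set(toggle_lts, phi) <= sat_set(
            toggle_lts, Modal("EAF", AAtom("I", "=", 0), phi)
        )

    def test_until_with_trivial_guard_equals_eaf(self, toggle_lts):
        psi = atom_pattern({"A": 0, "B": 1})
        until = sat_set(toggle_lts, Modal("EAU", ATrue(), TrueF(), psi))
        eaf = sat_set(toggle_lts, Modal("EAF", ATrue(), psi))
        assert until == eaf

    def test_unknown_atom_rejected(self, toggle_lts):
        with pytest.raises(FormulaTypeError, match="unknown"):
            sat_set(toggle_lts, Atom("Z", "=", 1))

    def test_alpha_over_non_input_rejected(self, toggle_lts):
        with pytest.raises(FormulaTypeError, match="non-input"):
            sat_set(toggle_lts, Modal("EAF", AAtom("A", "=", 1), TrueF()))

    def test_state_atom_over_input_rejected(self, toggle_lts):
        with pytest.raises(FormulaTypeError, match="input"):
            sat_set(toggle_lts, Atom("I", "=", 1))


class TestCheck:
    def test_reach_and_hold_pb_under_i0(self, toggle_lts):
        pb = atom_pattern({"A": 0, "B": 1})
        alpha = AAtom("I", "=", 0)
        formula = Modal("EAF", alpha, And(pb, Modal("AAG", alpha, pb)))
        result = check(toggle_lts, {"A": 1, "B": 0}, formula)
        assert result.holds
        assert result.counterexample == frozenset()

    def test_deadlocked_initial_state_fails_reachability(self, toggle_lts):
        result = check(
            toggle_lts,
            {"A": 0, "B": 1},
            Modal("EAF", ATrue(), atom_pattern({"A": 1, "B": 0})),
        )
        assert not result.holds
        assert result.counterexample == frozenset({(0, 1)})

    def test_whole_initial_set_convention(self, toggle_lts):
        # init A=0 covers (0,0) and (0,1); only (0,0) can reach PA under I=1
        result = check(
            toggle_lts,
            Atom("A", "=", 0),
            Modal("EAF", AAtom("I", "=", 1), atom_pattern({"A": 1, "B": 0})),
        )
        assert not result.holds
        assert result.counterexample == frozenset({(0, 1)})
        assert result.witness == frozenset({(0, 0)})

    def test_empty_initial_set_is_vacuous_not_false(self, toggle_lts):
        with pytest.raises(VacuousPropertyError):
            contradiction = And(Atom("A", "=", 1), Atom("A", "=", 0))
            check(toggle_lts, contradiction, TrueF())


def _random_lts(seed):
    model = fixtures.random_model(
        2 + seed % 2, 1 + seed % 2, max_levels=1, seed=seed
    )
    return build_lts(model)


def _some_alphas(lts):
    out = [ATrue()]
    if lts.input_names:
        out.append(AAtom(lts.input_names[0], "=", 0))
        out.append(ANot(AAtom(lts.input_names[0], "=", 0)))
    return out


def _some_phis(lts):
    name = lts.names[0]
    return [TrueF(), Atom(name, "=", 0), Not(Atom(name, "=", 0))]


class TestAlgebraicProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_aag_is_dual_to_eaf(self, seed):
        lts = _random_lts(seed)
        states = set(lts.states)
        for alpha in _some_alphas(lts):
            for phi in _some_phis(lts):
                aag = sat_set(lts, Modal("AAG", alpha, phi))
                eaf_neg = sat_set(lts, Modal("EAF", alpha, Not(phi)))
                assert aag == states - eaf_neg

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_eaf_monotone_in_phi_and_alpha(self, seed):
        lts = _random_lts(seed)
        name = lts.names[0]
        phi1 = atom_pattern({name: 0})
        phi2 = TrueF()  # phi1 implies phi2
        for alpha in _some_alphas(lts):
            s1 = sat_set(lts, Modal("EAF", alpha, phi1))
            s2 = sat_set(lts, Modal("EAF", alpha, phi2))
            assert s1 <= s2
        if lts.input_names:
            a1 = AAtom(lts.input_names[0], "=", 0)  # a1 implies true
            s_restricted = sat_set(lts, Modal("EAF", a1, phi1))
            s_free = sat_set(lts, Modal("EAF", ATrue(), phi1))
            assert s_restricted <= s_free

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_singleton_alpha_reduces_to_ctl_on_fixed_input_stg(self, seed):
        model = fixtures.random_model(2 + seed % 2, 1, max_levels=1, seed=seed)
        lts = build_lts(model)
        for value in (0, 1):
            inputs = {model.input_names[0]: value}
            stg = full_stg(model, inputs)
            alpha = AAtom(model.input_names[0], "=", value)
            phi_states = {s for s in lts.states if s[0] == 0}
            got = sat_set(lts, Modal("EAF", alpha, Atom(lts.names[0], "=", 0)))
            # plain CTL EF: backward reachability on the fixed-input STG
            expected = set(phi_states)
            frontier = set(phi_states)
            pred = {}
            for a, b in stg.graph.edges:
                pred.setdefault(b, set()).add(a)
            while frontier:
                new = set()
                for t in frontier:
                    new |= pred.get(t, set()) - expected
                expected |= new
                frontier = new
            assert got == expected


class TestOracleEquivalence:
    def test_fixpoints_match_path_enumeration(self):
        for model in battery_models(20, seed_base=900, max_levels=1):
            lts = build_lts(model)
            if len(lts.states) > 16:
                continue
            for alpha in _some_alphas(lts):
                vals = lts.alpha_valuations(alpha)
                for phi in _some_phis(lts):
                    phi_states = sat_set(lts, phi)
                    assert sat_set(lts, Modal("EAF", alpha, phi)) == (
                        exhaustive.eaf_by_paths(lts, vals, phi_states)
                    )
                    assert sat_set(lts, Modal("EAG", alpha, phi)) == (
                        exhaustive.eag_by_paths(lts, vals, phi_states)
                    )
                psi_states = sat_set(lts, _some_phis(lts)[1])
                assert sat_set(
                    lts, Modal("EAU", alpha, TrueF(), _some_phis(lts)[1])
                ) == exhaustive.eau_by_paths(
                    lts, vals, sat_set(lts, TrueF()), psi_states
                )
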