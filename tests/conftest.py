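import pytest

from logimc import arctl, fixtures
from logimc.stable import PhenotypePattern


@pytest.fixture
def toggle():
    return fixtures.toggle()


@pytest.fixture
def negative_circuit():
    return fixtures.negative_circuit()


@pytest.fixture
def step():
    return fixtures.step()


@pytest.fixture
def toggle_lts(toggle):
    return arctl.build_lts(toggle)


@pytest.fixture
def toggle_patterns():
    return {
        "PA": PhenotypePattern("PA", {"A": 1, "B": 0}),
        "PB": PhenotypePattern("PB", {"A": 0, "B": 1}),
    }


@pytest.fixture
def toggle_envs():
    return {"e0": {"I": 0}, "e1": {"I": 1}}


def battery_models(count, seed_base=0, max_levels=2):
    """Deterministic spread of small random models for oracle batteries."""
    out = []
    for k in range(count):
        n_components = 2 + k % 3  # 2..4 internal components
        n_inputs = k % 3  # 0..2 inputs
        out.append(
            fixtures.random_model(
                n_components,
                n_inputs,
                max_levels=1 + (k % 2) * (max_levels - 1),
                seed=seed_base + k,
            )
        )
    return out
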