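import numpy as np
import pytest

from mtcea import (
    CostSchedule,
    Group,
    ModelSpec,
    SimConfig,
    TransitionSchedule,
    UtilitySet,
    simulate_trial,
)
from mtcea.fixtures import table2_panel


@pytest.fixture(scope="session")
def state_table():
    """Packaged state-table fixture (counts and mean utilities)."""
    return table2_panel()


@pytest.fixture(scope="session")
def default_trial():
    """One default-sized synthetic trial (40 index / 38 control)."""
    return simulate_trial(SimConfig(seed=11))


def make_spec(
    u_protocol_index=0.7,
    u_protocol_control=0.7,
    u_recovered=0.8,
    u_non_recovered=0.6,
    cost_per_cycle=0.0,
    p_recover=0.0,
    p_relapse=0.0,
    n_cycles=32,
    discount_rate=0.0,
    **kwargs,
):
    """Small constant-schedule model spec for engine tests."""
    utilities = UtilitySet(u_protocol_index, u_protocol_control, u_recovered, u_non_recovered)
    costs = CostSchedule({g: np.full(n_cycles, float(cost_per_cycle)) for g in Group}, n_cycles=n_cycles)
    transitions = TransitionSchedule(
        {g: np.full(n_cycles, float(p_recover)) for g in Group},
        {g: np.full(n_cycles, float(p_relapse)) for g in Group},
        n_cycles=n_cycles,
    )
    return ModelSpec(
        utilities=utilities,
        costs=costs,
        transitions=transitions,
        horizon=n_cycles * 3,
        discount_rate=discount_rate,
        **kwargs,
    )


def random_spec(rng, n_cycles=32):
    """Arbitrary valid model spec drawn from a seeded generator."""
    utilities = UtilitySet(*rng.uniform(0, 1, size=4))
    costs = CostSchedule({g: rng.uniform(0, 5000, size=n_cycles) for g in Group}, n_cycles=n_cycles)
    transitions = TransitionSchedule(
        {g: rng.uniform(0, 1, size=n_cycles) for g in Group},
        {g: rng.uniform(0, 1, size=n_cycles) for g in Group},
        n_cycles=n_cycles,
    )
    return ModelSpec(
        utilities=utilities,
        costs=costs,
        transitions=transitions,
        horizon=n_cycles * 3,
        discount_rate=float(rng.uniform(0, 0.1)),
    )
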