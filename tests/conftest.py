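import numpy as np
import pytest

from fruitbox import (
    AgentParams,
    build_schedule,
    make_contingency,
    simulate_session,
)


@pytest.fixture(scope="session")
def contingency():
    return make_contingency(3)


@pytest.fixture(scope="session")
def schedule(contingency):
    return build_schedule(contingency, 4)


@pytest.fixture(scope="session")
def example_session(contingency, schedule):
    """One deterministic simulated session at mid-range parameters."""
    return simulate_session(AgentParams(0.3, 0.4), contingency, schedule, seed=5)


def spawn_seeds(master: int, n: int, per: int = 3) -> np.ndarray:
    """n independent rows of `per` integer seeds, derived from one master."""
    rows = []
    for ss in np.random.SeedSequence(master).spawn(n):
        rows.append(np.random.default_rng(ss).integers(2**31, size=per))
    return np.asarray(rows)
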