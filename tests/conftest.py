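import numpy as np
import pytest

from pinealnorm import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (78 ASD / 90 relatives / 47 controls)."""
    return generate_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def scaled_cohort():
    """Default cohort at 20x group sizes, for Monte-Carlo-tolerance checks."""
    return generate_cohort(SimulationConfig(seed=7).scaled(20))


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
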