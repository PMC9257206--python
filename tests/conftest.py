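import numpy as np
import pytest

from ricascade import (default_config, load_reference_study,
                       reference_ladders, reference_transition_tables,
                       simulate_dataset)

@pytest.fixture(scope="session")
def reference_study():
    return load_reference_study()


@pytest.fixture(scope="session")
def reference_tables():
    return reference_transition_tables()


@pytest.fixture(scope="session")
def published_ladders():
    return reference_ladders()


@pytest.fixture
def rng():
    return np.random.default_rng(20220622)


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic three-species study under a fixed seed."""
    return simulate_dataset(default_config(seed=11))
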