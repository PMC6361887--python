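import numpy as np
import pytest

from magnotrain.cohort import default_config, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def scenario_table():
    """One study-shaped cohort, shared across read-only tests."""
    return generate_cohort(default_config(), seed=7)
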