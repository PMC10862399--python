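import numpy as np
import pytest

from trdburden import build_base_case, default_generator_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A quick synthetic cohort for record-level and estimation tests."""
    return generate_cohort(default_generator_config(n_patients=4000, seed=11))


@pytest.fixture(scope="session")
def base_case():
    """A fully derived base case at reduced cohort size (shared, read-only)."""
    return build_base_case(seed=11, n_patients=8000)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
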