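import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

from gaitent import CohortSpec, generate_cohort, preprocess_recording


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """Small cohort for cheap end-to-end unit checks."""
    return CohortSpec(n_healthy=4, n_diseased=4, rng_seed=123)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def healthy_recording(tiny_cohort):
    return tiny_cohort[0]


@pytest.fixture(scope="session")
def healthy_steps(healthy_recording):
    return preprocess_recording(healthy_recording)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
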