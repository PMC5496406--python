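import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mitipkpd as m

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_spec():
    return m.reference_population()


@pytest.fixture(scope="session")
def typical_individual(reference_spec):
    return m.realize_individual(reference_spec)


@pytest.fixture(scope="session")
def study_times():
    return np.asarray(m.SAMPLING_TIMES)


@pytest.fixture(scope="session")
def small_dataset():
    """18-subject synthetic study with the published design."""
    return m.generate(seed=2024)
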