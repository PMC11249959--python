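import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fib_dirs():
    """Deterministic quasi-uniform unit directions generator."""
    def make(n):
        i = np.arange(n)
        golden = (1 + 5 ** 0.5) / 2
        z = 1 - 2 * (i + 0.5) / n
        theta = 2 * np.pi * i / golden
        r = np.sqrt(1 - z ** 2)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return make


@pytest.fixture(scope="session")
def default_cohort():
    from dtialps import CohortSpec, make_cohort
    return make_cohort(CohortSpec(seed=7))


@pytest.fixture(scope="session")
def default_phantom():
    from dtialps import PhantomSpec, make_phantom
    return make_phantom(PhantomSpec(seed=3))
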