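import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=25, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gene_params():
    """Benchmark parameter set for the self-regulated gene network."""
    return {"r0": 2.0, "r1": 10.0, "n": 4.0, "gamma0": 1.0, "b": 0.2, "omega": 200.0}


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
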