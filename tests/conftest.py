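import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rossler_ensemble():
    """25 coupled-Rossler realizations at the benchmark defaults (N=2048).

    Shared across the acceptance-style ensemble tests; simulation dominates
    the cost, so it runs once per session.
    """
    from pccc import RosslerConfig, simulate_coupled_rossler

    return [
        simulate_coupled_rossler(RosslerConfig(seed=k)) for k in range(25)
    ]


@pytest.fixture(scope="session")
def rossler_pair(rossler_ensemble):
    """A single representative realization."""
    return rossler_ensemble[0]
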