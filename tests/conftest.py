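import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trscore.simulate import SimulationConfig, simulate_bundle

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config():
    """A small but signal-bearing study configuration."""
    return SimulationConfig(
        n_genes=150,
        n_tissues=3,
        n_cases=60,
        n_controls=60,
        causal_fraction=0.05,
        expr_effect=0.5,
        n_pcs=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """(truth, annotation, panels, expression, cohort, coloc) for tests."""
    return simulate_bundle(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
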