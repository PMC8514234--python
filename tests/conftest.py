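import numpy as np
import pytest

from clusterkin import ClusterPopulation, KineticParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_population():
    return ClusterPopulation(np.array([1.0, 2.0, 3.0, 5.0, 8.0]))


@pytest.fixture
def full_model_params():
    """The strongest size-dependent aggregation setting of the full model."""
    return KineticParams(
        r=0.5,
        K=1000.0,
        beta=0.5,
        nu_F=2 / 3,
        alpha=1e-3,
        nu_A=2 / 3,
        lambda_=0.01,
        nu_E=1 / 3,
    )
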