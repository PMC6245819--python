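import numpy as np
import pytest

from mutburden import simulate


@pytest.fixture(scope="session")
def small_feature_cohort():
    """Feature-only cohort (no latent factor, no drivers), n=2000 genes."""
    return simulate.generate_cohort(
        simulate.SimulationConfig.feature_only(seed=11, n_genes=2000)
    )


@pytest.fixture(scope="session")
def tiny_default_cohort():
    """Default study-conditions cohort scaled to 400 genes, 4 drivers."""
    config = simulate.SimulationConfig.default(seed=5, n_genes=400)
    config.drivers = simulate.DriverSpec(n_ts=2, n_og=2)
    return simulate.generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
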