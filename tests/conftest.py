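import numpy as np
import pytest

from phenogrowth.synthetic import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """8 genotypes x 2 treatments x 3 reps x 12 days, default noise."""
    cfg = SimConfig(n_genotypes=8, n_reps=3, n_days=12, seed=11)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def noisefree_experiment():
    cfg = SimConfig(
        n_genotypes=4,
        n_reps=2,
        n_days=10,
        residual_sd=0.0,
        feature_noise_sd=0.0,
        water_noise_sd=0.0,
        genotype_rate_sd=0.0,
        seed=3,
    )
    return simulate_experiment(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
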