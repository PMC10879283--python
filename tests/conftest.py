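import numpy as np
import pytest

from ftdx import SimulationConfig, WScoreHarmonizer, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Paper-scale class imbalance shrunk ~4x for fast tests."""
    config = SimulationConfig(
        n_per_class={"bvFTD": 44, "nfvPPA": 16, "svPPA": 12}, seed=11
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def full_cohort():
    """Default study conditions: 173/63/41, d=2 planted atrophy."""
    return generate_cohort(SimulationConfig(seed=5))


@pytest.fixture(scope="session")
def harmonized_small(small_table):
    model = WScoreHarmonizer().fit(small_table)
    return model, model.transform(small_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
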