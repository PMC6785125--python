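import numpy as np
import pytest

from cdtkit import (
    SubstitutionModel,
    TwoEpochModel,
    simulate_coalescent,
    simulate_sequences,
)

#: study-scale generating conditions: ~100-fold post-glacial expansion with a
#: mutation-scaled transition time matching a ~12 kya event at ~2e-8/site/yr
EXPANSION_MODEL = dict(
    kind="logistic", theta_modern=0.02, theta_ancient=0.0002, transition_time=2.5e-4
)


@pytest.fixture(scope="session")
def hky_gamma():
    return SubstitutionModel(kappa=4.0, gamma_shape=0.5)


@pytest.fixture(scope="session")
def expansion_alignment(hky_gamma):
    """One 40 x 608 alignment simulated under the strong-expansion TEM."""
    model = TwoEpochModel(**EXPANSION_MODEL)
    gen = simulate_coalescent(40, model, seed=3)
    return simulate_sequences(gen, hky_gamma, 608, seed=4)


@pytest.fixture(scope="session")
def constant_model():
    return TwoEpochModel("exponential", 0.01, 0.01, 1.0)


def random_genealogy(n, seed, kind="exponential"):
    model = TwoEpochModel(kind, 0.02, 0.0005, 3e-4)
    return simulate_coalescent(n, model, seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
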