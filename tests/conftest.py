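import numpy as np
import pytest

from chainstab import EnsembleConfig, MetaCommunityState, SpeciesPool, sample_pool


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_species_pool():
    """The hand-checkable 2-species pool used across the dynamics examples."""
    return SpeciesPool(
        r1=np.array([1.0, 1.0]),
        r2=np.array([1.0, 1.0]),
        A=np.array([[-1.0, 0.5], [-0.5, -1.0]]),
    )


@pytest.fixture
def random_pool(rng):
    return sample_pool(EnsembleConfig(N=8, richness_range=(1, 8)), rng)


@pytest.fixture
def small_pool(rng):
    return sample_pool(EnsembleConfig(N=3, richness_range=(1, 3)), rng)


def random_state(pool, rng, p_present=0.6, scale=1.0):
    n = pool.N
    x1 = rng.uniform(0.05, scale, n) * (rng.uniform(size=n) < p_present)
    x2 = rng.uniform(0.05, scale, n) * (rng.uniform(size=n) < p_present)
    return MetaCommunityState(x1, x2)
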