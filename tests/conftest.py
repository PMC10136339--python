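import numpy as np
import pytest

from emgforce import PoolParams, build_pool, MuscleGeometry, TripoleSpec


@pytest.fixture(scope="session")
def pool():
    """Default 150-unit pool (reverse onion skin, 40% recruitment range)."""
    return build_pool(PoolParams())


@pytest.fixture(scope="session")
def small_pool():
    """A 20-unit pool for cheap end-to-end runs."""
    return build_pool(PoolParams(n_units=20))


@pytest.fixture(scope="session")
def geometry():
    return MuscleGeometry()


@pytest.fixture(scope="session")
def tripole():
    return TripoleSpec()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
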