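import numpy as np
import pytest

from spacesvg.geometry import SpotSet, default_kernel_bank, pairwise_distances


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_spots():
    """120 spots uniform on the unit square."""
    gen = np.random.default_rng(42)
    coords = gen.uniform(size=(120, 2))
    return SpotSet(tuple(f"s{i}" for i in range(120)), coords)


@pytest.fixture(scope="session")
def small_bank(small_spots):
    return default_kernel_bank(pairwise_distances(small_spots))
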