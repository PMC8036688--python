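import numpy as np
import pytest

from luces import (
    DriverStack,
    LandUseMap,
    default_truth,
    evolve_map,
    gen_drivers,
    gen_initial_map,
)


def lum(array, cell_size=30.0):
    """Shorthand to build a LandUseMap from a nested list."""
    return LandUseMap(np.asarray(array, dtype=np.int16), cell_size)


@pytest.fixture(scope="session")
def drivers_small() -> DriverStack:
    return gen_drivers((24, 24), n_point_sources=2, corr_length=3.0, seed=11)


@pytest.fixture(scope="session")
def truth_small(drivers_small):
    return default_truth(len(drivers_small.names), seed=5)


@pytest.fixture(scope="session")
def map_pair_small(drivers_small, truth_small):
    t0 = gen_initial_map(drivers_small, truth_small, smoothing_passes=1)
    t1 = evolve_map(t0, truth_small, seed=21)
    return t0, t1


@pytest.fixture(scope="session")
def map_pair_large():
    """256×256 snapshot pair used for statistical recovery checks."""
    drv = gen_drivers((256, 256), n_point_sources=4, corr_length=8.0, seed=3)
    truth = default_truth(len(drv.names), seed=3)
    t0 = gen_initial_map(drv, truth, smoothing_passes=0)
    t1 = evolve_map(t0, truth, seed=17)
    return t0, t1, truth
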