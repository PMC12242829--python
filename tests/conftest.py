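import numpy as np
import pytest

from spherofiber.builder import spheroid_complex
from spherofiber.fixtures import make_fixture, regular_tetrahedron_cell


@pytest.fixture(scope="session")
def cube():
    return make_fixture("single_cube_cell")


@pytest.fixture(scope="session")
def two_cell():
    return make_fixture("two_cell")


@pytest.fixture(scope="session")
def five_cell():
    return make_fixture("five_cell_short_edge")


@pytest.fixture(scope="session")
def tetra():
    return regular_tetrahedron_cell()


@pytest.fixture(scope="session")
def small_spheroid():
    """A 60-cell spheroid cut-out shared by read-only tests."""
    return spheroid_complex(60, np.random.default_rng(42))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def sweep():
    """The solid/fluid target-shape-index ensemble at p = 0.8 (the expensive
    shared computation: 5 values of s0 x 3 seeds at the reduced scale)."""
    from spherofiber.studies import solid_fluid_sweep
    return solid_fluid_sweep(seed=1, keep_trajectories=True)


@pytest.fixture(scope="session")
def sweep_p09():
    """Matched-conditions ensemble at p = 0.9 for the ordering comparisons."""
    from spherofiber.studies import solid_fluid_sweep
    return solid_fluid_sweep(seed=1, s0_grid=(5.2, 5.8),
                             keep_trajectories=True, p=0.9)
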