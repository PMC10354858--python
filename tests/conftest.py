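import numpy as np
import pytest

from vmatqa import simulate as sim


@pytest.fixture(scope="session")
def geometry():
    return sim.make_detector_geometry()


@pytest.fixture(scope="session")
def small_dataset():
    """8 beams (4 train / 2 validation / 2 test) with default physics."""
    return sim.generate_dataset(n_beams=8, split=(4, 2, 2), seed=11)


@pytest.fixture(scope="session")
def small_plan():
    return sim.sample_plan(5)


@pytest.fixture(scope="session")
def small_dose(small_plan, geometry):
    grid, planar = sim.compute_dose(small_plan, geometry)
    return grid, planar


@pytest.fixture(scope="session")
def smooth_field():
    """A smooth, rotationally non-symmetric 3D field for resampling tests."""
    n, spacing = 31, 2.5
    ax = (np.arange(n) - n // 2) * spacing
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    r2 = x**2 + y**2 + z**2
    vals = np.exp(-r2 / (2 * 30.0**2)) * (1.0 + 0.3 * np.sin(x / 17.0)
                                          + 0.2 * np.cos(z / 23.0))
    return ax, vals
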