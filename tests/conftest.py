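import numpy as np
import pytest

from pamnet.geometry import MediumProperties, ROIGrid, ReceiverArray, preset_config


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def f612():
    """Medium, array, grid, frequency for the 612 kHz preset."""
    return preset_config("f612")


@pytest.fixture(scope="session")
def desk_grid():
    """21^3 grid over the same 10 mm cube at 4 cm (0.5 mm pitch)."""
    return ROIGrid(axial_distance=0.04, voxel_pitch=0.5e-3)


@pytest.fixture(scope="session")
def tiny_grid():
    """5^3 grid for brute-force beamforming oracles."""
    return ROIGrid(axial_distance=0.04, side_length=4e-3, voxel_pitch=1e-3)


def gaussian_blob(shape, center, sigma, amplitude=1.0):
    """Axis-aligned Gaussian intensity blob on a voxel grid (test fixture)."""
    idx = np.indices(shape, dtype=float)
    q = sum(((idx[a] - center[a]) / sigma[a]) ** 2 for a in range(3))
    return amplitude * np.exp(-0.5 * q)
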