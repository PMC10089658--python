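import numpy as np
import pytest

from retao.shwfs import LensletArray, find_centroids, reference_frame
from retao.zernike import PupilGrid, Wavefront


@pytest.fixture(scope="session")
def grid() -> PupilGrid:
    """Default metrology grid (256 samples across the pupil)."""
    return PupilGrid(256)


@pytest.fixture(scope="session")
def small_grid() -> PupilGrid:
    return PupilGrid(128)


@pytest.fixture(scope="session")
def lenslets() -> LensletArray:
    return LensletArray()


@pytest.fixture(scope="session")
def reference(grid, lenslets):
    """Centroided reference frame of the flat wavefront."""
    return find_centroids(reference_frame(grid, lenslets))


@pytest.fixture
def flat(grid) -> Wavefront:
    return Wavefront(grid, np.zeros((grid.n_samples,) * 2))
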