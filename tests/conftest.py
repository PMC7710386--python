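import numpy as np
import pytest

from patternblend import KineticParams, make_grid_mesh


@pytest.fixture(scope="session")
def default_params():
    return KineticParams()


@pytest.fixture(scope="session")
def grid64():
    return make_grid_mesh(64, 64, periodic=True)


@pytest.fixture(scope="session")
def disk_image():
    """Rasterized disk of radius 50 px, centred in a 201x201 frame."""
    yy, xx = np.mgrid[0:201, 0:201]
    return (yy - 100) ** 2 + (xx - 100) ** 2 <= 50**2
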