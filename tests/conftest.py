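import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spirct import (
    Geometry,
    PhantomSpec,
    build_jaw_phantom,
    default_spectrum,
    get_projector,
    make_bin_scheme,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_geometry():
    """Fast fan-beam geometry for unit tests."""
    return Geometry(n_detector=96, detector_pitch=0.19, n_views=90)


@pytest.fixture(scope="session")
def small_grid():
    """(n_pixels, pixel_size) matched to small_geometry's field of view."""
    return 64, 0.2


@pytest.fixture(scope="session")
def small_projector(small_geometry, small_grid):
    return get_projector(small_geometry, *small_grid)


@pytest.fixture(scope="session")
def small_phantom():
    """Desk-scale jaw phantom rasterized on a coarse 128-pixel grid."""
    return build_jaw_phantom(PhantomSpec(grid_size=128, pixel_size=0.1))


@pytest.fixture(scope="session")
def small_phantom_geometry():
    return Geometry(n_detector=128, detector_pitch=0.14, n_views=60)


@pytest.fixture(scope="session")
def spectrum():
    return default_spectrum()


@pytest.fixture(scope="session")
def bins(spectrum):
    return make_bin_scheme(spectrum=spectrum)


@pytest.fixture(scope="session")
def disk_image(small_grid):
    """Uniform off-center disk with known attenuation, plus its geometry."""
    n, h = small_grid
    coords = (np.arange(n) - (n - 1) / 2) * h
    x = coords[np.newaxis, :]
    y = coords[:, np.newaxis]
    mu = np.where(x**2 + (y + 0.5) ** 2 <= 9.0, 0.22, 0.0)
    return mu
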