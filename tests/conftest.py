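import numpy as np
import pytest

from megarray.basis import MultipoleBasisSpec
from megarray.geometry import HelmetShell3D, HelmetSurface, SensorArray, radial_array


@pytest.fixture(scope="session")
def surface() -> HelmetSurface:
    """Default 2D helmet surface (R = 0.15 m, 0.15 m band, pi/2 opening)."""
    return HelmetSurface()


@pytest.fixture(scope="session")
def shell() -> HelmetShell3D:
    """Default 3D helmet shell (0.15-0.25 m)."""
    return HelmetShell3D()


@pytest.fixture(scope="session")
def small_spec() -> MultipoleBasisSpec:
    """A small expansion (n = 15) that keeps matrix tests fast."""
    return MultipoleBasisSpec(l_max_internal=3, l_max_external=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_surface_array(
    surface: HelmetSurface, m: int, rng: np.random.Generator
) -> SensorArray:
    """Random admissible array: uniform surface parameters, random unit
    orientations."""
    pos = surface.point_from_params(rng.uniform(0, 1, m), rng.uniform(0, 1, m))
    ori = rng.normal(size=(m, 3))
    ori /= np.linalg.norm(ori, axis=1, keepdims=True)
    return SensorArray(pos, ori)
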