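import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from carotidcs.phantom import PhantomSpec, build_phantom


def small_spec(**overrides) -> PhantomSpec:
    """A reduced grid that keeps every geometric feature but runs fast."""
    kwargs = dict(
        grid_shape=(40, 48, 20),
        voxel_mm=(0.625, 0.625, 1.4),
        lumen_radius_mm=3.0,
        wall_thickness_mm=1.0,
        bifurcation_z_mm=4.0,
        branch_separation_mm=9.0,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def spec_small() -> PhantomSpec:
    return small_spec()


@pytest.fixture(scope="session")
def phantom_small(spec_small):
    return build_phantom(spec_small)


@pytest.fixture(scope="session")
def spec_default() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture(scope="session")
def phantom_default(spec_default):
    return build_phantom(spec_default)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
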