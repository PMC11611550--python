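import numpy as np
import pytest

from smartpet.phantom import PhantomSpec, build_phantom, make_cohort


@pytest.fixture(scope="session")
def spec32():
    return PhantomSpec(grid_shape=(32, 32, 32), voxel_size_mm=(5.0, 5.0, 5.0),
                       total_counts_standard=2_000_000, seed=7)


@pytest.fixture(scope="session")
def phantom32(spec32):
    return build_phantom(spec32)


@pytest.fixture(scope="session")
def cohort6(spec32):
    subjects, manifest = make_cohort(6, spec32)
    return subjects, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
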