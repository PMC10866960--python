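import numpy as np
import pytest

from sabrrad.imaging import ImageVolume, RoiMask
from sabrrad.phantom import PhantomParams, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Six phantom cases at default study conditions (shared, read-only)."""
    return generate_cohort(PhantomParams(n_cases=6, prevalence=0.5, seed=11))


@pytest.fixture(scope="session")
def one_case(small_cohort):
    return small_cohort[0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_volume(arr, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return ImageVolume(np.asarray(arr, dtype=np.float32), spacing, origin)


def make_mask(arr, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0), **kw):
    return RoiMask(np.asarray(arr, dtype=bool), spacing, origin, **kw)
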