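import numpy as np
import pytest

from gland3d import PhantomSpec, generate_case


@pytest.fixture(scope="session")
def small_spec():
    """A fast, small-geometry phantom spec used across unit tests."""
    return PhantomSpec(volume_shape=(40, 96, 96), n_glands=2,
                       lumen_radius_um=10.0, epithelium_thickness_um=7.2,
                       n_decoys=2, decoy_radius_um=9.0,
                       tortuosity=0.2, branching_prob=0.0, seed=7)


@pytest.fixture(scope="session")
def small_case(small_spec):
    return generate_case(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
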