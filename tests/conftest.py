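import numpy as np
import pytest

from qt1pipe.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def bowl_phantom():
    """Small uniform-tissue phantom with the polynomial B1 bowl."""
    return make_phantom(PhantomSpec(grid_shape=(24, 24, 24), rois_per_hemisphere=3))


@pytest.fixture(scope="session")
def flat_phantom():
    """Same geometry with a perfectly uniform transmit field (kappa = 1)."""
    return make_phantom(
        PhantomSpec(grid_shape=(24, 24, 24), rois_per_hemisphere=3,
                    b1_model="uniform", b1_range=(1.0, 1.0))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
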