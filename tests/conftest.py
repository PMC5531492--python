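import numpy as np
import pytest

from lungmech import PhantomSpec, generate
from lungmech.phantom import HyperRegion


@pytest.fixture(scope="session")
def small_identity_pair():
    """24-cube identity-deformation pair (independent noise draws only)."""
    return generate(PhantomSpec(shape=(24, 24, 24), spacing=(2.5,) * 3, seed=11))


@pytest.fixture(scope="session")
def small_hyper_pair():
    """32-cube pair with a hyper-expanding core (target delta* = 0.6)."""
    spec = PhantomSpec(
        shape=(32, 32, 32),
        spacing=(2.5,) * 3,
        seed=5,
        hyper_region=HyperRegion(radius=16.0, target_delta_star=0.6),
    )
    return generate(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
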