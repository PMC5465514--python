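import numpy as np
import pytest

from cardioviz.geometry_io import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Reduced phantom (40x40x50) for render/geometry tests."""
    spec = PhantomSpec.scaled((40, 40, 50))
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def default_phantom():
    """The full-size default phantom (60x60x80)."""
    return generate_phantom(PhantomSpec())


@pytest.fixture
def rng():
    return np.random.default_rng(42)
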