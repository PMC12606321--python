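import numpy as np
import pytest

from bbtquant.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default-configuration phantom, shared across tests."""
    return generate_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def ellipse_phantom():
    """Wobble-free phantom: the lesion mask is the plain discrete ellipse."""
    return generate_phantom(PhantomConfig(contour_wobble=0.0, lesion_radii=(50.0, 30.0)))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
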