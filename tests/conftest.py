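import numpy as np
import pytest

from mammocalc.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def phantom_pos():
    """One 128x128 positive phantom (5 scattered spots, contrast 0.5)."""
    spec = PhantomSpec(width=128, height=128, n_spots=5, spot_contrast=0.5, seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def phantom_neg():
    spec = PhantomSpec(width=128, height=128, n_spots=0, seed=11)
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
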