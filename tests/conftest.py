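import numpy as np
import pytest

from detrusor import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom with a 2.6 mm wall (13 px at 0.2 mm/px)."""
    spec = PhantomSpec(speckle_scale=0.0, blur_sigma_px=0.0, wall_thickness_mm=2.6)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def speckled_phantom():
    """Default-noise phantom (full Rayleigh speckle, blur)."""
    return generate_phantom(PhantomSpec(wall_thickness_mm=3.4, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
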