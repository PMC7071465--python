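import numpy as np
import pytest

from texslic import PhantomSpec, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def clean_phantom():
    """Noiseless two-region (grays 50/200) phantom with exact truth."""
    img, truth, _ = generate_phantom(PhantomSpec(seed=1))
    return img, truth


@pytest.fixture
def gradient_image():
    """A smooth ramp with texture-free structure, 32x32."""
    row = np.linspace(20, 230, 32)
    return np.round(np.tile(row, (32, 1))).astype(np.uint8)
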