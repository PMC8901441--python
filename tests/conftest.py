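import numpy as np
import pytest


def render_gaussian(shape, row, col, amplitude, sigma, background=0.0):
    """Pixel-center-sampled isotropic 2-D Gaussian (forward model oracle)."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return background + amplitude * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2.0 * sigma**2)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
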