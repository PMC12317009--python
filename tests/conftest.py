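import numpy as np
import pytest

from cytoborder import make_laminar_model


@pytest.fixture
def agranular_model():
    """Five-layer pattern lacking an inner granular peak (premotor-like)."""
    return make_laminar_model([0.1, 0.3, 0.3, 0.1, 0.2],
                              [0.60, 0.40, 0.30, 0.50, 0.45],
                              noise_sd=0.03, name="A")


@pytest.fixture
def contrast_model():
    """Same layering but two layer densities shifted by >= 0.15."""
    return make_laminar_model([0.1, 0.3, 0.3, 0.1, 0.2],
                              [0.60, 0.55, 0.30, 0.50, 0.60],
                              noise_sd=0.03, name="B")


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
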