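import numpy as np
import pytest

from triscope import OpticalConfig


@pytest.fixture
def small_config():
    """Smallest stack the subvolume rule allows (31 planes, 15 px / 15 plane
    half-widths) — keeps PSF tests fast while exercising the full chain."""
    return OpticalConfig(z_range=(-1500.0, 1500.0), z_step=100.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
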