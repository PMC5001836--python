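import numpy as np
import pytest

from screenpolish.synthetic_screen import ScreenDesign, generate_field


@pytest.fixture
def small_design():
    """2-plate, full 384-well design with mild noise and no hits."""
    return ScreenDesign(n_plates=2, noise_sd=0.05, seed=11)


@pytest.fixture
def noiseless_field():
    """30 non-overlapping noiseless cells, ratio ~ N(2.0, 0.3)."""
    nuclear, reporter, gt = generate_field(30, 2.0, 0.3, image_size=512, seed=3)
    return nuclear, reporter, gt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
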