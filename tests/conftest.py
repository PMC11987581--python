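import numpy as np
import pytest

from sticsflow import ImageSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_series(rng):
    """Small nonnegative random series with the reference calibration."""
    frames = rng.uniform(1.0, 10.0, size=(6, 24, 24))
    return ImageSeries(frames, pixel_size=0.14, frame_interval=15.0,
                       origin_note="raw")
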