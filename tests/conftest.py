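import numpy as np
import pytest

from ccgan.data import ImageSample, SynthConfig, generate_synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny imbalanced phantom dataset shared by training-level tests."""
    cfg = SynthConfig(n_samples=16, image_size=32, foreground_fraction=0.05,
                      n_lesions_range=(1, 2), seed=99)
    return generate_synthetic(cfg)


@pytest.fixture
def checkerboard_sample():
    img = np.indices((32, 32)).sum(axis=0) % 2 * 200.0 + 20.0
    mask = np.zeros((32, 32), dtype=np.int64)
    mask[4:9, 5:12] = 1
    return ImageSample("checker", img[:, :, None], mask)
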