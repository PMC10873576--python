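import numpy as np
import pytest

from panelselect import (
    MultichannelDataset,
    MultichannelImage,
    SyntheticConfig,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_image(rng):
    """A 4-channel 16x16 raw image with positive intensities."""
    pixels = rng.gamma(2.0, 10.0, size=(4, 16, 16))
    return MultichannelImage(pixels, ("CD3", "CD8", "CD20", "DAPI"))


@pytest.fixture(scope="session")
def noiseless_dataset():
    """The rank-3 noiseless benchmark: 12 markers, 64x64, split 4/2/2."""
    return generate_dataset(SyntheticConfig())


@pytest.fixture(scope="session")
def noisy_dataset():
    return generate_dataset(SyntheticConfig(noise_sd=0.1))


def make_dataset(channels_per_image, names, normalized="z"):
    """Build a tiny dataset from explicit per-split channel arrays."""
    def imgs(arrs):
        return [MultichannelImage(np.asarray(a, dtype=float), names, normalized) for a in arrs]

    train, val, *rest = channels_per_image
    test = rest[0] if rest else []
    return MultichannelDataset(imgs(train), imgs(val), imgs(test))
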