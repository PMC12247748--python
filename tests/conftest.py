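import numpy as np
import pytest

from germquant import OrientedSample


def make_sample(
    channel_values, mask=None, channel_names=None, sample_id="test"
) -> OrientedSample:
    """Build an OrientedSample from one or more 2-D channel arrays."""
    channels = [np.asarray(c, dtype=np.float64) for c in channel_values]
    image = np.stack(channels)
    if mask is None:
        mask = np.ones(image.shape[1:], dtype=bool)
    if channel_names is None:
        channel_names = tuple(f"ch{i}" for i in range(len(channels)))
    return OrientedSample(
        image=image, mask=np.asarray(mask, dtype=bool),
        channel_names=channel_names, sample_id=sample_id,
    )


def random_masked_sample(rng, shape=(32, 32), n_channels=1):
    """A random sample with a random (but valid) connected-ish blob mask."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    # random axis-aligned ellipse, guaranteed >= 2 columns and nonempty
    a = rng.uniform(w * 0.2, w * 0.45)
    b = rng.uniform(h * 0.2, h * 0.45)
    cy, cx = h / 2 + rng.uniform(-2, 2), w / 2 + rng.uniform(-2, 2)
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    image = rng.uniform(0, 1000, size=(n_channels, h, w))
    image[:, ~mask] = 0
    names = tuple(f"ch{i}" for i in range(n_channels))
    return OrientedSample(image=image, mask=mask, channel_names=names)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
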