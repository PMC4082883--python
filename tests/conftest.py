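import numpy as np
import pytest

import lumpwire as lw


@pytest.fixture(scope="session")
def disk_phantom():
    """Noiseless high-contrast circular lump with its ground truth."""
    return lw.make_lump_phantom(lw.disk_spec())


@pytest.fixture(scope="session")
def textured_phantom():
    """Low-contrast, haloed, textured, noisy lump (seed 0)."""
    return lw.make_lump_phantom(lw.textured_spec(0))


@pytest.fixture(scope="session")
def blob_features():
    """Two well-separated spherical blobs of 2-D feature vectors, 100 points
    each, laid out on a 10x20 'image' (left half cluster A, right half B)."""
    rng = np.random.default_rng(42)
    mu_a, mu_b = np.array([0.0, 0.0]), np.array([3.0, 3.0])
    feats = np.empty((10, 20, 2))
    feats[:, :10] = mu_a + rng.normal(0, 0.02, size=(10, 10, 2))
    feats[:, 10:] = mu_b + rng.normal(0, 0.02, size=(10, 10, 2))
    labels = np.zeros((10, 20), dtype=np.int64)
    labels[:, 10:] = 1
    return lw.FeatureStack(features=feats), labels, np.vstack([mu_a, mu_b])


@pytest.fixture()
def ramp_image():
    """I(r, c) = c / (cols - 1) on a 16x24 grid."""
    cols = 24
    px = np.tile(np.arange(cols) / (cols - 1), (16, 1))
    return lw.IntensityImage(px)
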