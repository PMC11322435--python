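import numpy as np
import pytest
from scipy import ndimage

from xmir.image_io import ImageRecord
from xmir.synthetic import SceneParams, generate_pairs


@pytest.fixture(scope="session")
def smooth_image():
    """A smooth random field in [0, 1] (bilinear-interpolation friendly)."""
    rng = np.random.default_rng(5)
    img = ndimage.gaussian_filter(rng.random((128, 128)), 2)
    img = (img - img.min()) / (img.max() - img.min())
    return ImageRecord(id="smooth", modality="A", pixels=img)


@pytest.fixture(scope="session")
def tiny_pairs():
    """Three small aligned synthetic pairs for fast training tests."""
    return generate_pairs(
        3, params=SceneParams(size=96, n_fibers=5, n_blobs=3), master_seed=3
    )
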