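import numpy as np
import pytest
from skimage.transform import resize

import lungprior as lp


@pytest.fixture(scope="session")
def phantom_pair():
    """One default phantom with its ground-truth lung mask."""
    return lp.generate_phantom(lp.PhantomSpec())


@pytest.fixture(scope="session")
def stage1(phantom_pair):
    """Full Stage-1 result on the default phantom (shared; ~6 s)."""
    img, _ = phantom_pair
    return lp.run_stage1(img)


@pytest.fixture(scope="session")
def stage1_truth(phantom_pair, stage1):
    """Ground truth resampled to the working resolution of the heuristic."""
    _, mask = phantom_pair
    shape = stage1.predicted_mask.shape
    return resize(mask.astype(float), shape, order=0,
                  anti_aliasing=False, preserve_range=True) > 0.5


@pytest.fixture(scope="session")
def tiny_channel_dataset():
    """Four 64x64 phantoms wrapped as channel sets with intensity-only priors.

    Cheap training fodder for harness tests that do not need the full
    heuristic: the prior planes carry the ground truth and blurred copies
    so that tiny networks can learn quickly.
    """
    from scipy.ndimage import gaussian_filter

    data = []
    for img, mask in lp.generate_suite(4, 7, "A", size=(64, 64)):
        m = mask.astype(np.float64)
        cs = lp.ChannelSet(
            image=img,
            cn1=np.clip(gaussian_filter(m, 1), 0, 1),
            cn2=np.clip(gaussian_filter(m, 2), 0, 1),
            log=m,
            pm=m,
        )
        data.append((cs, mask))
    return data


def rng_images(n, shape=(16, 16), seed=0):
    rng = np.random.default_rng(seed)
    return [rng.uniform(0.0, 1.0, size=shape) for _ in range(n)]
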