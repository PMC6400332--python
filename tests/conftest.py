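import numpy as np
import pytest

from petctseg.labels import SlicePair, make_labels
from petctseg.phantom import PhantomConfig, generate_phantom

#: Coarse CT grid (2 mm in-plane) keeps network-facing tests fast while
#: preserving the default bladder geometry in mm.
SMALL_CFG = PhantomConfig(ct_shape=(12, 64, 64), ct_spacing=(4.0, 2.0, 2.0), noise_sd=2.0, seed=7)


@pytest.fixture(scope="session")
def small_case():
    return generate_phantom(SMALL_CFG)


@pytest.fixture(scope="session")
def small_pairs(small_case):
    return make_labels(small_case.pet, small_case.ct)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_pair(rng, shape=(16, 16), patient_id="p0"):
    image = rng.integers(-1000, 2000, size=shape).astype(np.float32)
    mask = (rng.random(shape) < 0.3).astype(np.uint8)
    return SlicePair(image=image, mask=mask, patient_id=patient_id)
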