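import numpy as np
import pytest

from lesiongan.image import ImageTensor, RANGE_UNIT
from lesiongan import synthetic_data as sd


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_rgb(rng):
    """A small random RGB image in [0, 1]."""
    return ImageTensor(rng.uniform(0, 1, (24, 24, 3)), RANGE_UNIT, "RGB")


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """A 24-image synthetic dataset on disk, shared across tests."""
    out = tmp_path_factory.mktemp("data")
    params = sd.SyntheticParams(n_images=24, image_side=32, seed=5)
    records = sd.make_dataset(params, out)
    return params, out, records
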