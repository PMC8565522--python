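import numpy as np
import pytest

from callosum.connectivity import dilate_labels, count_connections, normalize
from callosum.generative import GenerativeModel
from callosum.phantom import make_phantom
from callosum.tracts import make_tractogram


@pytest.fixture(scope="session")
def phantom():
    return make_phantom(7)


@pytest.fixture(scope="session")
def phantom17():
    return make_phantom(17)


@pytest.fixture(scope="session")
def dilated(phantom):
    return dilate_labels(phantom.network_labels, 2.0, phantom.grid.voxel_size)


@pytest.fixture(scope="session")
def model():
    return GenerativeModel.default()


@pytest.fixture(scope="session")
def clean_tractogram(phantom):
    """All-network bundle with zero jitter and no off-target streamlines."""
    counts = {n: 40 for n in range(1, phantom.k + 1)}
    return make_tractogram(phantom, counts, endpoint_jitter_mm=0.0,
                           off_target_fraction=0.0, crossing_jitter_mm=0.0, seed=11)


@pytest.fixture(scope="session")
def clean_probability_map(phantom, dilated, clean_tractogram):
    cmap = count_connections(clean_tractogram, phantom.cc_mask, dilated,
                             phantom.grid, k=phantom.k, subject_id="sub-0001")
    return normalize(cmap)


def make_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
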