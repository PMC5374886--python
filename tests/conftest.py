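import numpy as np
import pytest
from hypothesis import settings

from netgof import NetworkAtlas, Volume3D, ZMap
from netgof.atlas import YEO7_NAMES
from netgof.volume import BinaryMask

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def random_atlas(shape=(8, 8, 8), k=7, seed=0, background_fraction=0.3):
    """Random labelled atlas: a fraction of voxels is background (0), the rest
    is partitioned into k networks, each guaranteed nonempty."""
    rng = np.random.default_rng(seed)
    n = int(np.prod(shape))
    labels = rng.integers(1, k + 1, size=n)
    labels[rng.random(n) < background_fraction] = 0
    for net in range(1, k + 1):  # guarantee every network has voxels
        if not (labels == net).any():
            labels[rng.choice(np.flatnonzero(labels == 0))] = net
    names = dict(YEO7_NAMES) if k == 7 else {i: f"net{i}" for i in range(1, k + 1)}
    return NetworkAtlas(labels.reshape(shape), 7 if k == 7 else 17, names)


def make_zmap(z, valid=None, subject_id="s"):
    z = np.asarray(z, dtype=float)
    if valid is None:
        valid = np.isfinite(z)
    return ZMap(z=Volume3D(z), subject_id=subject_id, valid=BinaryMask(valid))


@pytest.fixture
def atlas7():
    return random_atlas(seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
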