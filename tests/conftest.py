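import numpy as np
import pytest

from peppertrack.geometry import BoundingBox


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_box(rng, max_pos=500.0, max_size=80.0) -> BoundingBox:
    return BoundingBox(
        left=float(rng.uniform(0, max_pos)),
        top=float(rng.uniform(0, max_pos)),
        width=float(rng.uniform(1.0, max_size)),
        height=float(rng.uniform(1.0, max_size)),
    )


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)
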