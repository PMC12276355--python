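import numpy as np
import pytest

from routescape.imaging import MultiplexImage


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_image(rng, h, w, n_channels=8):
    """A random valid multiplex image with the four common roles."""
    pix = rng.random((h, w, n_channels)) + 0.05
    roles = {"dapi": 0, "af": 1, "tumor": 2, "vessel": 3}
    for i in range(4, n_channels):
        roles[f"prot{i}"] = i
    return MultiplexImage(pix, roles)
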