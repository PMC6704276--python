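import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20190701)


def random_invertible_affine(rng, scale=5.0):
    """A random affine transform guaranteed well away from singular."""
    from msi2lmd import AffineTransform2D

    while True:
        a, b, c, d = rng.normal(0, scale, 4)
        if abs(a * d - b * c) > 0.5:
            break
    tx, ty = rng.normal(0, 20.0, 2)
    return AffineTransform2D((a, b, tx, c, d, ty))
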