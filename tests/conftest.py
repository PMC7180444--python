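import math

import numpy as np
import pytest

from octfluid.phantom import PhantomSpec, generate_bscan


@pytest.fixture(scope="session")
def default_phantom():
    """One default-spec phantom with speckle, cysts, shadows and drusen."""
    return generate_bscan(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def clean_phantom():
    """A noise-free, lesion-free phantom (pure layered template)."""
    spec = PhantomSpec(n_cysts=0, n_shadows=0, n_drusen=0,
                       speckle_shape=math.inf, seed=7)
    return generate_bscan(spec), spec


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_blocks(n, max_side=12, min_side=5, seed=0, lo=0, hi=256):
    """Random uint8-valued test blocks of varying small sizes."""
    g = np.random.default_rng(seed)
    blocks = []
    for _ in range(n):
        h = int(g.integers(min_side, max_side + 1))
        w = int(g.integers(min_side, max_side + 1))
        blocks.append(g.integers(lo, hi, size=(h, w)).astype(float))
    return blocks
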