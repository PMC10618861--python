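import numpy as np
import pytest

from osteorom.synthetic_vertebrae import ChainRecipe, VertebraParams, make_chain, make_vertebra

COARSE = dict(centrum_segments=10, facet_divisions=(4, 3))


@pytest.fixture(scope="session")
def default_vertebra():
    vert, truth = make_vertebra(VertebraParams(), "C4")
    return vert, truth


@pytest.fixture(scope="session")
def pair_chain():
    """Two vertebrae, one joint, default parameters."""
    return make_chain(ChainRecipe(n_vertebrae=2))


@pytest.fixture(scope="session")
def three_chain():
    """Three vertebrae, two joints, default parameters."""
    return make_chain(ChainRecipe(n_vertebrae=3))


@pytest.fixture(scope="session")
def four_chain_coarse():
    """Four vertebrae, three joints, coarse meshes (for grid sweeps)."""
    return make_chain(ChainRecipe(n_vertebrae=4, base=VertebraParams(**COARSE)))


def scan_axis_limit(ctx, axis: int, direction: int, step: float = 2.0, max_angle: float = 88.0):
    """Largest viable single-axis deflection found by stepping outward."""
    angle = 0.0
    while abs(angle + direction * step) <= max_angle:
        trial = [0.0, 0.0, 0.0]
        trial[axis] = angle + direction * step
        if not ctx.classify(*trial).viable:
            break
        angle += direction * step
    return angle


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
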