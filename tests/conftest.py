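import numpy as np
import pytest

from rodcell import phantom as ph
from rodcell import rodscule as rod


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def one_cell_spec():
    """A single horizontal 60x14 px rod cell, no spots, no noise."""
    cell = ph.CellPhantom(center=(48, 32), length=60, width=14)
    return ph.PhantomSpec(image_shape=(64, 96), cells=(cell,), noise_std=0.0)


@pytest.fixture
def one_cell_clean(one_cell_spec):
    clean, _noisy, truth = ph.render(one_cell_spec)
    return clean, truth


def random_state(rng, span=60.0):
    """A random non-degenerate rodscule state (rejection sampled)."""
    while True:
        pts = rng.uniform(10, 10 + span, (3, 2))
        try:
            geo = rod.geometry_from_points(
                rod.RodsculeState(tuple(pts[0]), tuple(pts[1]),
                                  tuple(pts[2])))
        except rod.DegenerateStateError:
            continue
        return rod.RodsculeState(tuple(pts[0]), tuple(pts[1]), tuple(pts[2]))
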