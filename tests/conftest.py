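import numpy as np
import pytest

from trackmigrate.track_io import Track


@pytest.fixture
def straight_track():
    """Ten collinear points along +x, 2 µm apart, 20 min frames."""
    n = 10
    return Track("straight", np.arange(n), np.column_stack([2.0 * np.arange(n), np.zeros(n)]))


@pytest.fixture
def l_track():
    """The 3-4-5 right-angle path (0,0) -> (3,0) -> (3,4)."""
    return Track("L", np.arange(3), np.array([[0.0, 0.0], [3.0, 0.0], [3.0, 4.0]]))


@pytest.fixture
def square_track():
    """Closed unit-square loop."""
    xy = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0], [0.0, 0.0]])
    return Track("square", np.arange(5), xy)


@pytest.fixture
def random_track_factory():
    def make(seed: int = 0, n: int = 20, scale: float = 3.0) -> Track:
        rng = np.random.default_rng(seed)
        xy = np.cumsum(rng.normal(0, scale, size=(n, 2)), axis=0)
        return Track(f"rnd{seed}", np.arange(n), xy)

    return make
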