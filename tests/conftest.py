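import numpy as np
import pytest

from netlyze.io_events import EventList, LocalizationSet
from netlyze.partition import Roi


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def collinear_events():
    """Three blinks on a line at x = 0, 15, 30 nm (hand-traceable merge)."""
    return EventList(points=np.array([[0.0, 0, 0], [15.0, 0, 0],
                                      [30.0, 0, 0]]))


@pytest.fixture
def triangle_points():
    """Equilateral triangle with 50 nm sides."""
    return np.array([[0.0, 0.0, 0.0],
                     [50.0, 0.0, 0.0],
                     [25.0, 25.0 * np.sqrt(3.0), 0.0]])


@pytest.fixture
def uniform_roi(rng):
    """A 3 x 3 x 1 um^3 ROI holding 400 uniform random points."""
    lo = np.zeros(3)
    hi = np.array([3000.0, 3000.0, 1000.0])
    pts = rng.uniform(lo, hi, size=(400, 3))
    return Roi(bounds=np.array([lo, hi]),
               points=LocalizationSet(points=pts),
               cell_id="cell0", roi_index=0)


def sphere_shell(n, radius, rng, center=(0.0, 0.0, 0.0)):
    """n points uniform on a sphere shell."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return np.asarray(center) + radius * v


def solid_ball(n, radius, rng, center=(0.0, 0.0, 0.0)):
    """n points uniform in a solid ball."""
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return np.asarray(center) + r * v
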