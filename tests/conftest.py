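import numpy as np
import pytest

from centmorph import CalibratedImage, PolygonROI


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_image():
    return CalibratedImage(np.full((64, 64), 5.0), pixel_size=0.1, unit="um")


@pytest.fixture
def random_image(rng):
    return CalibratedImage(rng.uniform(0, 100, size=(32, 32)),
                           pixel_size=0.1, unit="um")


@pytest.fixture
def irregular_roi():
    # half-integer vertices keep every pixel center strictly in or out,
    # so boundary conventions cannot differ between implementations
    return PolygonROI([[3.5, 2.5], [24.5, 4.5], [28.5, 18.5], [15.5, 27.5],
                       [5.5, 20.5]], kind="freehand")


def brute_force_region_pixels(shape, vertices):
    """Independent point-in-polygon test: matplotlib even-odd rule."""
    from matplotlib.path import Path

    h, w = shape
    path = Path(vertices)
    xs, ys = np.meshgrid(np.arange(w), np.arange(h))
    pts = np.column_stack([xs.ravel(), ys.ravel()])
    inside = path.contains_points(pts)
    return inside.reshape(h, w)
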