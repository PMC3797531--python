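import numpy as np
import pytest

import tissuesim as ts


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_square():
    return ts.tissue_from_polygons([np.array([[0., 0.], [1., 0.],
                                              [1., 1.], [0., 1.]])])


@pytest.fixture
def two_squares():
    return ts.tissue_from_polygons([
        np.array([[0., 0.], [1., 0.], [1., 1.], [0., 1.]]),
        np.array([[1., 0.], [2., 0.], [2., 1.], [1., 1.]])])


@pytest.fixture
def hex19():
    """Two-ring centered hexagonal tissue (19 cells)."""
    return ts.hex_template(2, side=1.0)


def random_convex_polygon(rng, n=8, radius=1.0):
    """Convex polygon from the hull of random points on an ellipse."""
    ang = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = radius * rng.uniform(0.6, 1.4, n)
    pts = np.column_stack([r * np.cos(ang), 0.7 * r * np.sin(ang)])
    from scipy.spatial import ConvexHull
    hull = ConvexHull(pts)
    return pts[hull.vertices]
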