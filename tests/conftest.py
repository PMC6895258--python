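import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from clutchscope.locdata_io import LocalizationTable, NuclearMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_mask():
    return NuclearMask(Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)]))


@pytest.fixture
def holed_mask():
    return NuclearMask(
        Polygon([(0, 0), (2000, 0), (2000, 2000), (0, 2000)]),
        [Point(1000, 1000).buffer(300, quad_segs=16)],
    )


def random_mask(rng, n_holes=0):
    """An irregular star-convex mask with optional disk exclusions."""
    angles = np.linspace(0, 2 * np.pi, 15, endpoint=False)
    radii = 1000.0 * (1.0 + 0.4 * rng.random(15))
    boundary = Polygon(np.column_stack([radii * np.cos(angles),
                                        radii * np.sin(angles)]))
    holes = []
    for _ in range(n_holes):
        for _ in range(100):
            c = rng.uniform(-500, 500, 2)
            hole = Point(c).buffer(rng.uniform(80, 200), quad_segs=12)
            if boundary.contains(hole) and all(not hole.intersects(h) for h in holes):
                holes.append(hole)
                break
    return NuclearMask(boundary, holes)


def table_from_xy(xy, **extra):
    xy = np.asarray(xy, float)
    return LocalizationTable.from_arrays(xy[:, 0], xy[:, 1], **extra)
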