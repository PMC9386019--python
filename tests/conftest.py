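import numpy as np
import pytest
from shapely.geometry import LineString

from wingmorph import segmentation
from wingmorph.fixtures import _poly_xy, make_damaged, make_wing


@pytest.fixture(scope="session")
def wing10():
    """Standard 10-cell wing fixture used across the suite."""
    return make_wing(n_cells=10, seed=1)


@pytest.fixture(scope="session")
def seg10(wing10):
    return segmentation.segment(wing10.image)


@pytest.fixture(scope="session")
def damaged_wing(wing10):
    """wing10 with the innermost cell swallowed by a hole, plus the seed
    pixel that marks the hole."""
    outline = _poly_xy(wing10.silhouette)
    ring = LineString(np.asarray(outline.exterior.coords))
    inner = max(range(len(wing10.cells)),
                key=lambda i: ring.distance(_poly_xy(wing10.cells[i])))
    hole = np.asarray(
        _poly_xy(wing10.cells[inner]).buffer(4).exterior.coords)[:, ::-1]
    dmg = make_damaged(wing10, [hole])
    centroid = hole.mean(axis=0)
    seed = (int(round(centroid[0])), int(round(centroid[1])))
    assert dmg.image[seed], "hole seed must land on a white pixel"
    return dmg, seed
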