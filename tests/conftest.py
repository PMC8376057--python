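import numpy as np
import pytest
from shapely.geometry import box

from habsel.landscape import (
    GridPatchMap,
    PolygonPatchMap,
    SurveySquare,
)


@pytest.fixture
def toy_square() -> SurveySquare:
    """200 m square centred at (100, 100): local coords span [0, 200]."""
    return SurveySquare("sqA", centroid=(100.0, 100.0), side_length=200.0)


@pytest.fixture
def half_plane_polygons(toy_square):
    """Left half habitat A, right half habitat B."""
    left = box(0, 0, 100, 200)
    right = box(100, 0, 200, 200)
    return PolygonPatchMap(toy_square, 2017, "rough",
                           [(left, "A"), (right, "B")])


def rasterize_half_plane(square: SurveySquare, cell_size: float,
                         legend=("A", "B")) -> GridPatchMap:
    """Grid version of the left/right half-plane map (split at x=100)."""
    n = int(round(square.side_length / cell_size))
    x0, y0, _, _ = square.bounds
    xs = x0 + (np.arange(n) + 0.5) * cell_size
    row = (xs >= 100.0).astype(np.int16)
    cells = np.tile(row, (n, 1))
    return GridPatchMap(square, 2017, "rough", cells, legend, cell_size)


@pytest.fixture
def half_plane_grid(toy_square) -> GridPatchMap:
    return rasterize_half_plane(toy_square, cell_size=1.0)


@pytest.fixture
def uniform_grid(toy_square) -> GridPatchMap:
    """Single-type square map (all arable)."""
    cells = np.zeros((200, 200), dtype=np.int16)
    return GridPatchMap(toy_square, 2017, "rough", cells, ("arable",), 1.0)


@pytest.fixture
def road_grid(toy_square) -> GridPatchMap:
    """Arable square with a single 10 m wide vertical road at x in [95, 105]."""
    cells = np.zeros((200, 200), dtype=np.int16)
    cells[:, 95:105] = 1
    return GridPatchMap(toy_square, 2017, "rough", cells,
                        ("arable", "road"), 1.0)
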