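import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from firehia.districts import District, DistrictLayer
from firehia.grid import ConcentrationGrid

CRS = "local-metre"


@pytest.fixture
def grid2x2():
    """One-day 2x2 grid, unit cells, values [[1,2],[3,4]] (row 0 at origin)."""
    values = np.array([[[1.0, 2.0], [3.0, 4.0]]])
    return ConcentrationGrid(
        values=values, x0=0.0, y0=0.0, cell_size=1.0, crs=CRS,
        timestamps=pd.DatetimeIndex(["2019-11-01"]),
    )


@pytest.fixture
def uniform_grid():
    """Three-day 5x5 grid of constant 42 µg/m³, 10 km cells."""
    values = np.full((3, 5, 5), 42.0)
    return ConcentrationGrid(
        values=values, x0=0.0, y0=0.0, cell_size=10_000.0, crs=CRS,
        timestamps=pd.date_range("2019-11-01", periods=3, freq="D"),
    )


@pytest.fixture
def left_column_layer():
    """Polygon exactly covering the left column of the unit 2x2 grid."""
    return DistrictLayer([District("left", box(0, 0, 1, 2))], crs=CRS)


@pytest.fixture
def full_layer():
    """Polygon covering the whole unit 2x2 grid."""
    return DistrictLayer([District("all", box(0, 0, 2, 2))], crs=CRS)


def make_layer(rects, crs=CRS, prefix="D"):
    """DistrictLayer from a list of (xmin, ymin, xmax, ymax) rectangles."""
    return DistrictLayer(
        [District(f"{prefix}{k}", box(*r)) for k, r in enumerate(rects)], crs=crs
    )
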