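"""Georeferenced concentration fields.

A :class:`ConcentrationGrid` is a regular rectangular raster of PM2.5
increments (µg/m³) with one 2-D slab per time step.  Cell values are
cell-averaged over the cell rectangle, not point samples.  The grid origin
``(x0, y0)`` is the outer corner of cell ``(0, 0)``; the row index
increases away from the origin along the y-axis, the column index along
the x-axis, so cell ``(i, j)`` covers

    x in [x0 + j*cell_size, x0 + (j+1)*cell_size]
    y in [y0 + i*cell_size, y0 + (i+1)*cell_size].

Persistence uses NetCDF (classic/NetCDF3 flavour through xarray's scipy
engine) with dims ``(time, y, x)`` and the georeference stored as global
attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
import xarray as xr

from firehia.errors import InvalidParameterError


@dataclass
class ConcentrationGrid:
    """Daily (or hourly) gridded concentration increments.

    Parameters
    ----------
    values
        Array of shape ``(n_times, ny, nx)``; NaN marks missing cells.
    x0, y0
        Outer corner of cell (0, 0) in grid CRS units.
    cell_size
        Cell edge length, in grid CRS units (metres for the default CRS).
    crs
        Named coordinate reference system (see :mod:`firehia.crs`).
    timestamps
        One timestamp per slab, strictly increasing.
    """

    values: np.ndarray
    x0: float
    y0: float
    cell_size: float
    crs: str
    timestamps: pd.DatetimeIndex = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise InvalidParameterError("values must be (time, y, x)")
        if self.cell_size <= 0:
            raise InvalidParameterError("cell_size must be positive")
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        if len(self.timestamps) != self.values.shape[0]:
            raise InvalidParameterError("one timestamp per time slab required")
        if len(self.timestamps) > 1 and not self.timestamps.is_monotonic_increasing:
            raise InvalidParameterError("timestamps must be monotone increasing")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def nx(self) -> int:
        return self.values.shape[2]

    @property
    def ny(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> Tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid rectangle."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.nx * self.cell_size,
            self.y0 + self.ny * self.cell_size,
        )

    def cell_bounds(self, i: int, j: int) -> Tuple[float, float, float, float]:
        """Rectangle (xmin, ymin, xmax, ymax) covered by cell (i, j)."""
        cs = self.cell_size
        return (
            self.x0 + j * cs,
            self.y0 + i * cs,
            self.x0 + (j + 1) * cs,
            self.y0 + (i + 1) * cs,
        )

    def cell_centers(self) -> Tuple[np.ndarray, np.ndarray]:
        """Center coordinates: (ys of rows, xs of columns)."""
        cs = self.cell_size
        ys = self.y0 + (np.arange(self.ny) + 0.5) * cs
        xs = self.x0 + (np.arange(self.nx) + 0.5) * cs
        return ys, xs

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x <= xmax and ymin <= y <= ymax

    def cell_index(self, x: float, y: float) -> Tuple[int, int]:
        """Index (i, j) of the cell containing the point.

        A point on an interior edge belongs to the lower-index cell, so the
        mapping is deterministic; a point outside the extent raises.
        """
        if not self.contains(x, y):
            raise InvalidParameterError(f"point ({x}, {y}) outside grid extent")
        j = _edge_index((x - self.x0) / self.cell_size, self.nx)
        i = _edge_index((y - self.y0) / self.cell_size, self.ny)
        return i, j

    # -- I/O ----------------------------------------------------------------

    def to_dataset(self) -> xr.Dataset:
        ys, xs = self.cell_centers()
        da = xr.DataArray(
            self.values,
            dims=("time", "y", "x"),
            coords={"time": self.timestamps, "y": ys, "x": xs},
            name="pm25",
            attrs={"units": "ug m-3", "long_name": "PM2.5 increment"},
        )
        ds = da.to_dataset()
        ds.attrs.update(
            {"x0": self.x0, "y0": self.y0, "cell_size": self.cell_size, "crs": self.crs}
        )
        return ds

    def to_netcdf(self, path: str | Path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path: str | Path) -> "ConcentrationGrid":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds.load()
        return cls(
            values=ds["pm25"].values,
            x0=float(ds.attrs["x0"]),
            y0=float(ds.attrs["y0"]),
            cell_size=float(ds.attrs["cell_size"]),
            crs=str(ds.attrs["crs"]),
            timestamps=pd.DatetimeIndex(ds["time"].values),
        )


def _edge_index(t: float, n: int) -> int:
    """Cell index along one axis for normalized coordinate t in [0, n].

    Interior edges (integer t) break ties toward the lower index; the outer
    edges t=0 and t=n map to the first and last cell respectively.
    """
    if t <= 0:
        return 0
    k = int(np.ceil(t)) - 1
    return min(k, n - 1)
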