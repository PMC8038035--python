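"""Zonal statistics: assign gridded daily increments to district polygons.

The overlay treats each grid cell as a rectangle carrying a cell-averaged
value.  For ``area_weighted`` the district mean is the intersection-area
weighted mean of all cells the polygon touches; for ``cell_center`` it is
the unweighted mean of cells whose centers fall strictly inside the
polygon.  Both methods agree exactly when district boundaries coincide
with cell boundaries.

Negative modelled increments are clamped to zero *after* averaging, since
the attribution model is defined only for non-negative increments.
"""

from __future__ import annotations

import warnings
from typing import Dict, List, Literal, Tuple

import numpy as np
import pandas as pd
from shapely.geometry import Point, box
from shapely.prepared import prep

from firehia.districts import DistrictLayer
from firehia.errors import CRSError, InvalidParameterError
from firehia.grid import ConcentrationGrid

# intersection pieces below this fraction of district area are geometric noise
SLIVER_FRACTION = 1e-9
COVERAGE_WARN = 0.9

Method = Literal["area_weighted", "cell_center"]


def _cell_range(lo: float, hi: float, origin: float, cs: float, n: int) -> range:
    """Indices of cells whose rectangles can intersect [lo, hi] on one axis."""
    first = max(int(np.floor((lo - origin) / cs)), 0)
    last = min(int(np.ceil((hi - origin) / cs)), n)
    return range(first, max(last, first))


def district_weights(
    grid: ConcentrationGrid, districts: DistrictLayer, method: Method = "area_weighted"
) -> Dict[str, Tuple[np.ndarray, np.ndarray, float]]:
    """Per-district flat cell indices and weights for the zonal overlay.

    Returns a mapping district_id -> (flat_indices, weights, district_area).
    For ``area_weighted`` the weights are intersection areas (slivers below
    ``SLIVER_FRACTION`` of the district area dropped); for ``cell_center``
    every selected cell has weight ``cell_size**2``.
    """
    if method not in ("area_weighted", "cell_center"):
        raise InvalidParameterError(f"unknown zonal method {method!r}")
    cs = grid.cell_size
    out: Dict[str, Tuple[np.ndarray, np.ndarray, float]] = {}
    for d in districts:
        geom = d.geometry
        area = geom.area
        xmin, ymin, xmax, ymax = geom.bounds
        rows = _cell_range(ymin, ymax, grid.y0, cs, grid.ny)
        cols = _cell_range(xmin, xmax, grid.x0, cs, grid.nx)
        prepared = prep(geom)
        idx: List[int] = []
        wts: List[float] = []
        for i in rows:
            for j in cols:
                cell = box(*grid.cell_bounds(i, j))
                if method == "cell_center":
                    center = Point(grid.x0 + (j + 0.5) * cs, grid.y0 + (i + 0.5) * cs)
                    if prepared.contains(center):
                        idx.append(i * grid.nx + j)
                        wts.append(cs * cs)
                else:
                    if not prepared.intersects(cell):
                        continue
                    w = cs * cs if prepared.contains(cell) else geom.intersection(cell).area
                    if w > SLIVER_FRACTION * area:
                        idx.append(i * grid.nx + j)
                        wts.append(w)
        out[d.district_id] = (np.asarray(idx, dtype=int), np.asarray(wts, dtype=float), area)
    return out


def zonal_mean(
    grid: ConcentrationGrid,
    districts: DistrictLayer,
    method: Method = "area_weighted",
    clamp_negative: bool = True,
) -> pd.DataFrame:
    """District × day mean increment with coverage fractions.

    Returns a DataFrame with columns ``district_id, date, delta_x,
    coverage``.  Coverage is the fraction of the district area overlain by
    valid (non-missing) grid cells; districts intersecting no cell yield
    missing values with a warning.  The mean is computed over the covered
    area only; a warning is emitted when coverage drops below 90%.
    """
    if grid.crs != districts.crs:
        raise CRSError(
            f"grid CRS {grid.crs!r} != district CRS {districts.crs!r}; reproject first"
        )
    weights = district_weights(grid, districts, method=method)
    flat = grid.values.reshape(grid.shape[0], -1)
    records = []
    for d in districts:
        idx, w, area = weights[d.district_id]
        if idx.size == 0:
            warnings.warn(f"district {d.district_id!r} intersects no grid cell")
        for t, ts in enumerate(grid.timestamps):
            vals = flat[t, idx] if idx.size else np.empty(0)
            valid = np.isfinite(vals)
            wsum = float(w[valid].sum()) if idx.size else 0.0
            if wsum > 0:
                mean = float(np.dot(w[valid], vals[valid]) / wsum)
                if clamp_negative:
                    mean = max(mean, 0.0)
                coverage = min(wsum / area, 1.0)
            else:
                mean, coverage = np.nan, 0.0
            records.append(
                {
                    "district_id": d.district_id,
                    "date": ts,
                    "delta_x": mean,
                    "coverage": coverage,
                }
            )
    df = pd.DataFrame.from_records(records)
    low = df[(df["coverage"] < COVERAGE_WARN) & (df["coverage"] > 0)]
    if not low.empty:
        worst = low.sort_values("coverage").iloc[0]
        warnings.warn(
            f"{low['district_id'].nunique()} district(s) with coverage < {COVERAGE_WARN}"
            f" (worst: {worst['district_id']!r} at {worst['coverage']:.3f})"
        )
    return df
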