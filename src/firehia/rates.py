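"""Areal projection of incidence rates between administrative layers.

Hospitalization rates are published on administrative polygons (local
government areas for cardiac, local health districts for respiratory)
that are not nested with the census exposure districts.  Each exposure
district receives the mean of the rates of all source polygons it
intersects — unweighted by default (``simple_mean``), or weighted by
intersection area (``area_weighted_mean``) for sensitivity analysis.
Intersections smaller than a sliver threshold (1e-6 of the target area)
are boundary-digitization artifacts and are ignored.
"""

from __future__ import annotations

from typing import Literal, Optional

import pandas as pd

from firehia.districts import DistrictLayer
from firehia.errors import CRSError, InvalidParameterError, MissingDataError

SLIVER_FRACTION = 1e-6

ProjectionMethod = Literal["simple_mean", "area_weighted_mean"]


def project_rates(
    source_layer: DistrictLayer,
    source_rates: pd.DataFrame,
    target_layer: DistrictLayer,
    method: ProjectionMethod = "simple_mean",
) -> pd.DataFrame:
    """Project rates from source polygons onto target district ids.

    ``source_rates`` has columns ``region_id, endpoint, rate`` (year-free;
    average over years first with :func:`average_rates_over_years`).
    Returns the same schema keyed by target district ids.  The projected
    rate always lies within [min, max] of the contributing source rates.
    """
    if method not in ("simple_mean", "area_weighted_mean"):
        raise InvalidParameterError(f"unknown projection method {method!r}")
    if source_layer.crs != target_layer.crs:
        raise CRSError(
            f"source CRS {source_layer.crs!r} != target CRS {target_layer.crs!r}"
        )
    rates = source_rates.copy()
    rates["region_id"] = rates["region_id"].astype(str)
    records = []
    for target in target_layer:
        tgeom = target.geometry
        contributors = []  # (region_id, overlap_area)
        for source in source_layer:
            if not tgeom.intersects(source.geometry):
                continue
            a = tgeom.intersection(source.geometry).area
            if a > SLIVER_FRACTION * tgeom.area:
                contributors.append((source.district_id, a))
        if not contributors:
            raise MissingDataError(
                f"target district {target.district_id!r} intersects no source region"
            )
        contrib = pd.DataFrame(contributors, columns=["region_id", "overlap"])
        for endpoint, grp in rates.groupby("endpoint"):
            merged = contrib.merge(grp, on="region_id", how="inner")
            if merged.empty:
                raise MissingDataError(
                    f"no {endpoint!r} rate for any source intersecting "
                    f"target {target.district_id!r}"
                )
            if method == "simple_mean":
                rate = merged["rate"].mean()
            else:
                rate = (merged["rate"] * merged["overlap"]).sum() / merged["overlap"].sum()
            records.append(
                {"region_id": target.district_id, "endpoint": endpoint, "rate": rate}
            )
    return pd.DataFrame.from_records(records)


def average_rates_over_years(
    rates: pd.DataFrame,
    years: Optional[list] = None,
    fill: Optional[Literal["available_mean"]] = None,
) -> pd.DataFrame:
    """Arithmetic mean of rates across the listed years, dropping ``year``.

    Every (region, endpoint) must carry all requested years unless
    ``fill="available_mean"`` permits averaging whatever years exist.
    """
    if "year" not in rates.columns:
        raise InvalidParameterError("rates table has no 'year' column")
    if years is not None:
        sub = rates[rates["year"].isin(years)]
        counts = sub.groupby(["region_id", "endpoint"])["year"].nunique()
        short = counts[counts < len(set(years))]
        if not short.empty and fill != "available_mean":
            key = short.index[0]
            raise MissingDataError(
                f"region {key[0]!r} endpoint {key[1]!r} lacks one of years {sorted(years)}"
            )
    else:
        sub = rates
    return sub.groupby(["region_id", "endpoint"], as_index=False)["rate"].mean()
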