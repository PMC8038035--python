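"""Polygon district layers (census districts, rate regions) with GeoJSON I/O."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from firehia.crs import get_transform
from firehia.errors import CRSError, InvalidParameterError


@dataclass
class District:
    district_id: str
    geometry: BaseGeometry
    name: Optional[str] = None


@dataclass
class DistrictLayer:
    """A set of identified polygons sharing one CRS.

    Invariants enforced at construction: unique ids and valid
    (non-self-intersecting) geometries.
    """

    districts: List[District]
    crs: str

    _by_id: Dict[str, District] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [d.district_id for d in self.districts]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidParameterError(f"duplicate district ids: {dupes}")
        for d in self.districts:
            if not d.geometry.is_valid:
                raise InvalidParameterError(f"invalid geometry for district {d.district_id!r}")
        self._by_id = {d.district_id: d for d in self.districts}

    def __len__(self) -> int:
        return len(self.districts)

    def __iter__(self):
        return iter(self.districts)

    def __getitem__(self, district_id: str) -> District:
        return self._by_id[district_id]

    @property
    def ids(self) -> List[str]:
        return [d.district_id for d in self.districts]

    def total_area(self) -> float:
        return sum(d.geometry.area for d in self.districts)

    # -- GeoJSON I/O --------------------------------------------------------

    def to_geojson(self, path: str | Path) -> None:
        features = []
        for d in self.districts:
            props = {"district_id": d.district_id}
            if d.name is not None:
                props["name"] = d.name
            features.append(
                {"type": "Feature", "properties": props, "geometry": mapping(d.geometry)}
            )
        doc = {"type": "FeatureCollection", "crs_name": self.crs, "features": features}
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_geojson(cls, path: str | Path, crs: Optional[str] = None) -> "DistrictLayer":
        doc = json.loads(Path(path).read_text())
        layer_crs = crs or doc.get("crs_name")
        if layer_crs is None:
            raise CRSError(f"no CRS recorded in {path} and none supplied")
        districts = [
            District(
                district_id=str(f["properties"]["district_id"]),
                geometry=shape(f["geometry"]),
                name=f["properties"].get("name"),
            )
            for f in doc["features"]
        ]
        return cls(districts=districts, crs=str(layer_crs))


def reproject_layer(layer: DistrictLayer, target_crs: str) -> DistrictLayer:
    """Transform every geometry into *target_crs*, preserving ids.

    Uses the affine transform registry in :mod:`firehia.crs`; an unknown
    CRS pair raises :class:`CRSError`.  The identity reprojection returns
    an equal layer.
    """
    tf = get_transform(layer.crs, target_crs)

    def _tf(coords):
        out = coords.copy()
        for k, (x, y) in enumerate(coords):
            out[k, 0], out[k, 1] = tf(x, y)
        return out

    districts = []
    for d in layer.districts:
        geom = shapely.transform(d.geometry, _tf)
        if geom.area <= 0:
            raise CRSError(f"reprojection collapsed district {d.district_id!r}")
        districts.append(District(d.district_id, geom, d.name))
    return DistrictLayer(districts=districts, crs=target_crs)
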