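"""Coordinate obfuscation by administrative-centroid snapping (step 5).

Precise site locations for protected subsets (US and Canada records, and
records from password-protected contributing databases) are not published:
each such coordinate is replaced by the geometric centroid of the
administrative subdivision containing it. Points that fall just outside
every polygon — coastal sites, border rounding — snap to the nearest unit.
Records outside the protected subsets are left byte-identical.

Boundary layers are consumed as GeoJSON FeatureCollections with a name/id
property (the ADM2 layers of the geoBoundaries database follow this form).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from shapely.geometry import Point, shape

from .records import RecordTable, parse_float
from .geoloc import format_coordinate

log = logging.getLogger(__name__)


@dataclass
class AdminUnit:
    """One administrative subdivision: id, polygon(s), centroid, area."""

    id: str
    geom: object  # shapely (Multi)Polygon
    properties: dict = field(default_factory=dict)

    @property
    def centroid(self):
        c = self.geom.centroid
        return (c.x, c.y)

    @property
    def area(self) -> float:
        """Planar area in squared degrees (analytic for synthetic grids)."""
        if "area" in self.properties:
            return float(self.properties["area"])
        return self.geom.area


class AdminLayer:
    """A set of administrative units supporting containment and nearest-unit
    queries with a deterministic tie-break (lexicographically smallest id)."""

    def __init__(self, units):
        self.units = sorted(units, key=lambda u: str(u.id))
        self._by_id = {str(u.id): u for u in self.units}
        if len(self._by_id) != len(self.units):
            raise ValueError("unit ids must be unique")

    def __len__(self):
        return len(self.units)

    def __iter__(self):
        return iter(self.units)

    def get(self, unit_id):
        return self._by_id.get(str(unit_id))

    @classmethod
    def from_geojson(cls, path, id_field: str = "shapeName") -> "AdminLayer":
        """Load a FeatureCollection; ``id_field`` names the id property."""
        with open(path, encoding="utf-8") as fh:
            gj = json.load(fh)
        units = []
        for i, feat in enumerate(gj.get("features", [])):
            props = feat.get("properties") or {}
            uid = props.get(id_field, f"feature-{i}")
            units.append(AdminUnit(str(uid), shape(feat["geometry"]), props))
        return cls(units)

    def to_geojson(self, path, id_field: str = "shapeName") -> None:
        from shapely.geometry import mapping
        feats = []
        for u in self.units:
            props = dict(u.properties)
            props[id_field] = u.id
            feats.append({"type": "Feature", "properties": props,
                          "geometry": mapping(u.geom)})
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def assign_admin(p, layer: AdminLayer) -> AdminUnit:
    """The unit containing point (lon, lat), else the nearest one.

    Ties at equal distance resolve to the lexicographically smallest unit
    id (the layer keeps its units in that order).
    """
    if len(layer) == 0:
        raise ValueError("layer must be non-empty")
    pt = Point(float(p[0]), float(p[1]))
    for u in layer:
        if u.geom.covers(pt):
            return u
    return min(layer, key=lambda u: (u.geom.distance(pt), str(u.id)))


@dataclass(frozen=True)
class MaskSelector:
    """Which records get masked: by listed country or by source dataset."""

    by_country: frozenset = frozenset({"USA", "Canada"})
    by_source: frozenset = frozenset({"GuedesBocinsky2018"})

    def matches(self, rec: dict) -> bool:
        if str(rec.get("Country", "")).strip() in self.by_country:
            return True
        sources = [s.strip() for s in str(rec.get("Source", "")).split(";")]
        return any(s in self.by_source for s in sources)


def obfuscate(table: RecordTable, layer: AdminLayer,
              selector: MaskSelector | None = None):
    """Snap the coordinates of selected records to admin-unit centroids.

    Returns ``(masked table, n_masked)``. Selected records without
    coordinates are left untouched with a logged warning; non-selected
    records are byte-identical to the input.
    """
    selector = selector or MaskSelector()
    df = table.df.copy()
    n_masked = 0
    for idx, rec in zip(df.index, df.to_dict("records")):
        if not selector.matches(rec):
            continue
        lon, lat = parse_float(rec.get("Long")), parse_float(rec.get("Lat"))
        if lon is None or lat is None:
            log.warning("record %s selected for masking but has no usable "
                        "coordinates; left untouched", rec.get("LabID"))
            continue
        cx, cy = assign_admin((lon, lat), layer).centroid
        df.at[idx, "Long"] = format_coordinate(cx)
        df.at[idx, "Lat"] = format_coordinate(cy)
        n_masked += 1
    return RecordTable(df, provenance=list(table.provenance)), n_masked
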