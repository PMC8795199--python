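"""Coordinate standardization and location verification (cleaning step 2).

Source compilations report coordinates in decimal degrees or in
degrees/minutes/seconds with hemisphere letters; a few carry projected
Northing/Easting pairs that cannot be interpreted without zone metadata.
This module detects the format of each coordinate string and converts it to
WGS84 decimal degrees — or refuses, never guessing.

It also implements the location-verification decision tree applied against
administrative boundary polygons: a point just outside its listed country is
assumed to be a rounding or GPS artefact and keeps its (downgraded)
location; a point far outside is tested with its axes swapped (a common
data-entry error); failing that, a US/Canada site identifier can still place
the record in a state or province; otherwise the coordinates are dropped.

All distances are great-circle metres on a sphere of radius 6,371,000 m,
measured to densified boundary vertices — no map projection is involved.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Point

from .records import is_blank

EARTH_RADIUS_M = 6_371_000.0
#: metres per degree of great-circle arc
_M_PER_DEG = EARTH_RADIUS_M * np.pi / 180.0


@dataclass(frozen=True)
class VerificationThresholds:
    """Distance cut-offs of the verification decision tree, in metres."""

    near_m: float = 500.0
    far_m: float = 10_000.0

    def __post_init__(self):
        if not (0 < self.near_m < self.far_m):
            raise ValueError("require 0 < near_m < far_m")


_DECIMAL_RE = re.compile(r"^[+-]?\d+(?:\.\d+)?$")
_DMS_RE = re.compile(
    r"""^\s*([+-]?\d+(?:\.\d+)?)\s*[°ºd]?               # degrees
        (?:\s*(\d+(?:\.\d+)?)\s*['′m]?)?                # minutes
        (?:\s*(\d+(?:\.\d+)?)\s*(?:["″s]|'')?)?         # seconds
        \s*([NSEWnsew])?\s*$""",
    re.VERBOSE,
)
_AXIS_HEMIS = {"lat": "NS", "lon": "EW"}
_AXIS_MAX = {"lat": 90.0, "lon": 180.0}


def parse_coordinate(text, axis: str):
    """Parse one coordinate string.

    Returns ``(value_in_decimal_degrees, format_tag)``; on failure the value
    is ``None`` and the tag names the problem (``"unparseable"`` or
    ``"out-of-range"``). Recognized formats: plain decimal degrees and
    degrees/minutes[/seconds] with a sign or trailing hemisphere letter.
    Anything else (including projected Northing/Easting) is refused.
    """
    if axis not in _AXIS_HEMIS:
        raise ValueError(f"axis must be 'lat' or 'lon', got {axis!r}")
    s = str(text).strip()
    if not s:
        return None, "unparseable"
    if _DECIMAL_RE.match(s):
        v = float(s)
        if abs(v) > _AXIS_MAX[axis]:
            return None, "out-of-range"
        return v, "decimal"
    m = _DMS_RE.match(s)
    if m:
        deg_s, minu_s, sec_s, hemi = m.groups()
        deg = float(deg_s)
        minu = float(minu_s) if minu_s else 0.0
        sec = float(sec_s) if sec_s else 0.0
        if minu >= 60 or sec >= 60:
            return None, "unparseable"
        if hemi is not None:
            if hemi.upper() not in _AXIS_HEMIS[axis]:
                return None, "unparseable"
            if deg < 0:
                return None, "unparseable"
        v = abs(deg) + minu / 60.0 + sec / 3600.0
        if deg < 0 or (hemi is not None and hemi.upper() in "SW"):
            v = -v
        if abs(v) > _AXIS_MAX[axis]:
            return None, "out-of-range"
        return v, "dms"
    return None, "unparseable"


def format_coordinate(value: float) -> str:
    """Canonical decimal-degree text: six decimals, trailing zeros trimmed."""
    s = f"{value:.6f}".rstrip("0").rstrip(".")
    return "0" if s in ("-0", "") else s


def haversine_m(a, b):
    """Great-circle distance in metres between (lon, lat) points.

    Accepts scalars or numpy arrays (broadcasting); symmetric; zero iff the
    points coincide.
    """
    lon1, lat1 = np.radians(np.asarray(a[0], float)), np.radians(np.asarray(a[1], float))
    lon2, lat2 = np.radians(np.asarray(b[0], float)), np.radians(np.asarray(b[1], float))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


class UnitLookupError(KeyError):
    """An administrative unit name absent from the boundary layer."""


def _boundary_samples(geom, spacing_m: float) -> np.ndarray:
    """Vertices of the geometry's boundary densified to ~spacing_m."""
    spacing_deg = spacing_m / _M_PER_DEG
    boundary = shapely.segmentize(geom.boundary, spacing_deg)
    return shapely.get_coordinates(boundary)


def distance_to_admin(p, layer, name, spacing_m: float = 100.0) -> float:
    """Metres from point (lon, lat) to the named unit of a boundary layer.

    Zero when the point lies inside or on the unit; otherwise the haversine
    distance to the nearest densified boundary vertex (default spacing
    100 m, configurable).
    """
    unit = layer.get(name)
    if unit is None:
        raise UnitLookupError(name)
    geom = unit.geom
    pt = Point(float(p[0]), float(p[1]))
    if geom.covers(pt):
        return 0.0
    coords = _boundary_samples(geom, spacing_m)
    d = haversine_m((float(p[0]), float(p[1])), (coords[:, 0], coords[:, 1]))
    return float(np.min(d))


# ---------------------------------------------------------------------------
# table-level coordinate standardization

def standardize_coordinates(table):
    """Convert every coordinate cell to canonical decimal degrees.

    Cells already in decimal degrees are reformatted; DMS cells are
    converted; a record whose non-blank coordinates cannot be interpreted
    (projected pairs, out-of-range values) has both coordinates cleared and
    its LocAccuracy set to 0 — the record itself is retained, since only
    its location is unusable. Returns ``(table, n_converted, n_cleared)``.
    """
    from .records import RecordTable

    df = table.df.copy()
    n_converted = n_cleared = 0
    for idx, rec in zip(df.index, df.to_dict("records")):
        lon_s, lat_s = rec.get("Long", ""), rec.get("Lat", "")
        if is_blank(lon_s) and is_blank(lat_s):
            continue
        lon, lon_tag = parse_coordinate(lon_s, "lon")
        lat, lat_tag = parse_coordinate(lat_s, "lat")
        if lon is None or lat is None:
            df.at[idx, "Long"] = df.at[idx, "Lat"] = ""
            df.at[idx, "LocAccuracy"] = "0"
            n_cleared += 1
            continue
        df.at[idx, "Long"] = format_coordinate(lon)
        df.at[idx, "Lat"] = format_coordinate(lat)
        if lon_tag != "decimal" or lat_tag != "decimal":
            n_converted += 1
    return RecordTable(df, provenance=list(table.provenance)), n_converted, n_cleared


# ---------------------------------------------------------------------------
# US/Canada site-identifier fallback

_SMITHSONIAN_RE = re.compile(r"^\s*(\d{1,2})\s*[A-Za-z]")
_BORDEN_RE = re.compile(r"^\s*([A-Za-z]{4})-?\d*")


class SiteIdMap:
    """State/province lookup for US Smithsonian trinomials and Canadian
    Borden-grid site identifiers.

    Backed by a CSV with columns ``kind,prefix,province``: kind
    ``smithsonian`` maps the leading state number of a trinomial (e.g.
    ``48SW123`` -> 48 -> Wyoming); kind ``borden`` maps leading Borden
    letter blocks. The bundled file carries the 50 Smithsonian state
    numbers; Borden blocks can be added by users with the full grid table.
    """

    def __init__(self, smithsonian: dict, borden: dict | None = None):
        self.smithsonian = {str(k): v for k, v in smithsonian.items()}
        self.borden = {str(k).upper(): v for k, v in (borden or {}).items()}

    @classmethod
    def from_csv(cls, path) -> "SiteIdMap":
        import csv as _csv
        smith, borden = {}, {}
        with open(path, encoding="utf-8") as fh:
            for row in _csv.DictReader(fh):
                if row["kind"].strip() == "smithsonian":
                    smith[str(int(row["prefix"]))] = row["province"]
                elif row["kind"].strip() == "borden":
                    borden[row["prefix"]] = row["province"]
        return cls(smith, borden)

    @classmethod
    def bundled(cls) -> "SiteIdMap":
        from importlib import resources
        ref = resources.files("c14scrub.data") / "siteid_regions.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def province_for(self, site_id):
        s = str(site_id).strip()
        if not s:
            return None
        m = _SMITHSONIAN_RE.match(s)
        if m:
            return self.smithsonian.get(str(int(m.group(1))))
        m = _BORDEN_RE.match(s)
        if m:
            block = m.group(1).upper()
            for k in range(len(block), 0, -1):
                if block[:k] in self.borden:
                    return self.borden[block[:k]]
        return None


# ---------------------------------------------------------------------------
# verification decision tree

def _classify(d: float, th: VerificationThresholds):
    if d == 0.0:
        return "match"
    if d <= th.near_m:
        return "near"
    if d <= th.far_m:
        return "far"
    return "off"


def verify_location(rec: dict, layer, th: VerificationThresholds | None = None,
                    siteid_map=None) -> tuple[dict, str]:
    """Apply the location-verification decision tree to one record.

    The record must carry coordinates and a listed admin unit name in
    ``Country`` (``Province`` takes precedence when present, mirroring the
    state/province-level check used for US and Canada). LocAccuracy is never
    increased. Returns the (possibly updated) record and an action tag.
    """
    from .records import parse_float  # local import to avoid cycle noise

    th = th or VerificationThresholds()
    rec = dict(rec)
    lon = parse_float(rec.get("Long"))
    lat = parse_float(rec.get("Lat"))
    unit_name = rec.get("Province") or rec.get("Country")
    if lon is None or lat is None or is_blank(unit_name):
        return rec, "skipped"
    la = rec.get("LocAccuracy")
    la_val = int(la) if str(la).strip().lstrip("-").isdigit() else 0

    def _downgrade(level):
        rec["LocAccuracy"] = str(min(la_val, level))

    d = distance_to_admin((lon, lat), layer, unit_name)
    cls = _classify(d, th)
    if cls == "match":
        return rec, "match"
    if cls == "near":
        _downgrade(2)
        return rec, "near-match"
    if cls == "far":
        _downgrade(1)
        return rec, "far-match"

    # axes swapped on entry? test the flipped point
    flipped = (lat, lon)
    if abs(flipped[1]) <= 90.0:
        d2 = distance_to_admin(flipped, layer, unit_name)
        cls2 = _classify(d2, th)
        if cls2 != "off":
            rec["Long"], rec["Lat"] = format_coordinate(lat), format_coordinate(lon)
            if cls2 == "near":
                _downgrade(2)
            elif cls2 == "far":
                _downgrade(1)
            return rec, "flipped-" + ("match" if cls2 == "match" else cls2 + "-match")

    # US/Canada fallback: a recognizable site identifier still places the
    # record at state/province level
    if siteid_map is not None:
        prov = siteid_map.province_for(rec.get("SiteID", ""))
        if prov is not None:
            rec["Province"] = prov
            rec["Long"] = rec["Lat"] = ""
            _downgrade(1)
            return rec, "siteid-fallback"

    rec["Long"] = rec["Lat"] = ""
    rec["LocAccuracy"] = "0"
    return rec, "unlocatable"
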