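"""Seeded synthetic raw tables with known injected error classes.

The generator emulates the heterogeneous multi-source compilations the
scrubbing pipeline consumes: schema-valid records carrying registered lab
codes, plausible ages/errors, and coordinates on a synthetic administrative
grid — plus, on demand, exactly-counted injections of every error class the
pipeline handles (unknown lab codes, DMS-formatted coordinates, true and
conflicting duplicates, out-of-range ages and errors, mojibake, records
requiring geomasking). Every injection is recorded in a truth log of
expected per-record fates, so a pipeline run can be checked record by
record. Fixtures target rule coverage, not statistical realism.

All randomness flows through one seeded numpy Generator; identical seeds
give identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .dedup import SOURCE_SEP, normalize_labid
from .geoloc import format_coordinate, parse_coordinate
from .geomask import AdminLayer, AdminUnit, assign_admin
from .records import COLUMNS, Reason, RecordTable, parse_float

#: lab-code prefixes used by the generator; all present in the bundled registry
_LAB_CODES = ["OxA", "Beta", "GrN", "AA", "Poz", "Wk", "Ua", "ETH"]
#: fictional gazetteer keeping textfix tests self-contained
SITE_NAMES = ["Barkåker", "Alsónémedi", "Vindheim", "Askvoll", "Granmo",
              "Høyfjell", "Lindås", "Myrvoll", "Steinbru", "Tørnby"]
_COUNTRIES = {"Vestland": "Borealia", "Ostmark": "Borealia",
              "Sudoria": "Australis", "Nordavia": "Borealia"}
_MATERIALS = ["charcoal", "bone", "shell", "wood"]
_SOURCES = ["SynthA", "SynthB"]

#: prefix guaranteed absent from the lab-code registry
UNKNOWN_PREFIX = "QQXX"


@dataclass(frozen=True)
class ErrorSpec:
    """Per-class injection counts; each count is exact."""

    unknown_lab: int = 0
    dms_coords: int = 0
    true_duplicates: int = 0
    age_conflicts: int = 0
    location_conflicts: int = 0
    bad_error: int = 0
    future_age: int = 0
    too_old: int = 0
    non_integer_age: int = 0
    corrupt_text: int = 0
    mask_targets: int = 0

    def total(self) -> int:
        return sum(getattr(self, f.name) for f in fields(self))


def generate_admin_grid(nx: int, ny: int, cell_deg: float = 1.0,
                        x0: float = 0.0, y0: float = 0.0,
                        prefix: str = "cell") -> AdminLayer:
    """Rectangular non-overlapping admin units with analytic centroids/areas."""
    from shapely.geometry import box
    if nx < 1 or ny < 1:
        raise ValueError("grid must have at least one cell per axis")
    units = []
    for i in range(nx):
        for j in range(ny):
            xmin, ymin = x0 + i * cell_deg, y0 + j * cell_deg
            geom = box(xmin, ymin, xmin + cell_deg, ymin + cell_deg)
            units.append(AdminUnit(f"{prefix}-{i:02d}-{j:02d}", geom,
                                   {"area": cell_deg ** 2}))
    return AdminLayer(units)


def generate_clean(n: int, seed: int, region=(0.0, 0.0, 10.0, 10.0),
                   n_sites: int | None = None) -> RecordTable:
    """A schema-valid table that passes the whole pipeline untouched."""
    rng = np.random.default_rng(seed)
    x0, y0, x1, y1 = region
    n_sites = n_sites if n_sites is not None else max(1, n // 4)
    countries = list(_COUNTRIES)
    site_pool = []
    for s in range(n_sites):
        country = countries[int(rng.integers(len(countries)))]
        site_pool.append({
            "SiteName": f"{SITE_NAMES[s % len(SITE_NAMES)]} {s // len(SITE_NAMES) + 1}",
            "Long": format_coordinate(round(rng.uniform(x0, x1), 4)),
            "Lat": format_coordinate(round(rng.uniform(y0, y1), 4)),
            "Country": country,
            "Continent": _COUNTRIES[country],
        })
    rows = []
    for i in range(n):
        site = site_pool[int(rng.integers(n_sites))]
        age = int(rng.integers(100, 50_001))
        error = int(rng.integers(15, min(age, 150) + 1))
        d13c = f"{rng.uniform(-28.0, -18.0):.1f}" if rng.random() < 0.7 else ""
        code = _LAB_CODES[int(rng.integers(len(_LAB_CODES)))]
        rows.append({
            "LabID": f"{code}-{100000 + i}",
            "Age": str(age), "Error": str(error),
            "Material": _MATERIALS[int(rng.integers(len(_MATERIALS)))],
            "Taxa": "", "d13C": d13c, "Method": "AMS", "Period": "",
            "SiteID": "", "SiteName": site["SiteName"],
            "Long": site["Long"], "Lat": site["Lat"],
            "LocAccuracy": str(int(rng.integers(2, 4))),
            "Country": site["Country"], "Province": "",
            "Region": site["Country"], "Continent": site["Continent"],
            "Source": _SOURCES[int(rng.integers(len(_SOURCES)))],
            "Reference": "Doe 2001",
        })
    df = pd.DataFrame(rows, columns=COLUMNS, dtype=str) if rows else \
        pd.DataFrame(columns=COLUMNS, dtype=str)
    return RecordTable(df, provenance=[f"synthetic(seed={seed})"])


def _to_dms(value: float, axis: str) -> str:
    hemi = ("N" if value >= 0 else "S") if axis == "lat" else ("E" if value >= 0 else "W")
    v = abs(value)
    deg = int(v)
    rem = (v - deg) * 60
    minutes = int(rem)
    seconds = round((rem - minutes) * 60, 2)
    if seconds >= 60:  # carry from rounding
        seconds -= 60
        minutes += 1
    if minutes >= 60:
        minutes -= 60
        deg += 1
    return f"{deg}°{minutes}'{seconds}\"{hemi}"


def inject_errors(table: RecordTable, spec: ErrorSpec, seed: int,
                  mask_layer: AdminLayer | None = None):
    """Inject each error class exactly per spec; return table + truth log.

    Victim rows are chosen disjointly, so every record triggers at most one
    rule. Duplicate-based classes append a second instance of their victim.
    The truth log has one row per LabID with the expected fate: whether a
    record survives, the multiset of graveyard reasons, the expected final
    coordinates and (for merged true duplicates) the expected Source.
    """
    df = table.df.copy().reset_index(drop=True)
    n = len(df)
    if spec.total() > n:
        raise ValueError(f"spec needs {spec.total()} victims but table has {n}")
    rng = np.random.default_rng(seed)
    victims = list(rng.permutation(n)[:spec.total()])
    if mask_layer is None:
        mask_layer = generate_admin_grid(10, 10, 1.0)

    truth = {}
    for idx in range(n):
        rec = df.loc[idx]
        truth[normalize_labid(rec["LabID"])] = {
            "kept": True, "reasons": [],
            "final_lon": parse_float(rec["Long"]),
            "final_lat": parse_float(rec["Lat"]),
            "final_source": None,
        }

    def take(k):
        out, victims[:] = victims[:k], victims[k:]
        return out

    appended = []

    for idx in take(spec.unknown_lab):
        old = df.at[idx, "LabID"]
        df.at[idx, "LabID"] = f"{UNKNOWN_PREFIX}-{idx}"
        truth.pop(normalize_labid(old))
        truth[normalize_labid(df.at[idx, "LabID"])] = {
            "kept": False, "reasons": [Reason.UNKNOWN_LAB.name],
            "final_lon": None, "final_lat": None, "final_source": None}

    for idx in take(spec.dms_coords):
        lon, lat = float(df.at[idx, "Long"]), float(df.at[idx, "Lat"])
        dms_lon, dms_lat = _to_dms(lon, "lon"), _to_dms(lat, "lat")
        df.at[idx, "Long"], df.at[idx, "Lat"] = dms_lon, dms_lat
        t = truth[normalize_labid(df.at[idx, "LabID"])]
        t["final_lon"] = parse_coordinate(dms_lon, "lon")[0]
        t["final_lat"] = parse_coordinate(dms_lat, "lat")[0]

    for idx in take(spec.true_duplicates):
        dup = df.loc[idx].copy()
        dup["Source"] = "SynthDup"
        appended.append(dup)
        t = truth[normalize_labid(dup["LabID"])]
        t["reasons"].append(Reason.TRUE_DUPLICATE.name)
        t["final_source"] = SOURCE_SEP.join(sorted({df.at[idx, "Source"], "SynthDup"}))

    for idx in take(spec.age_conflicts):
        dup = df.loc[idx].copy()
        dup["Age"] = str(int(dup["Age"]) + 100)
        dup["Source"] = "SynthConf"
        appended.append(dup)
        t = truth[normalize_labid(dup["LabID"])]
        t.update(kept=False, final_lon=None, final_lat=None,
                 reasons=[Reason.AGE_MISMATCH.name] * 2)

    for idx in take(spec.location_conflicts):
        dup = df.loc[idx].copy()
        dup["Long"] = format_coordinate(round(float(dup["Long"]) + 0.7, 4))
        dup["Source"] = "SynthConf"
        appended.append(dup)
        t = truth[normalize_labid(dup["LabID"])]
        t.update(kept=False, final_lon=None, final_lat=None,
                 reasons=[Reason.LOCATION_CONFLICT.name] * 2)

    simple = [
        ("bad_error", {"Error": "14"}, Reason.ERROR_TOO_SMALL),
        ("future_age", {"Age": "0"}, Reason.NONPOSITIVE_AGE),
        ("too_old", {"Age": "56000"}, Reason.AGE_TOO_OLD),
        ("non_integer_age", {"Age": None}, Reason.NON_INTEGER_AGE),
    ]
    for name, patch, reason in simple:
        for idx in take(getattr(spec, name)):
            for col, val in patch.items():
                df.at[idx, col] = val if val is not None else f"{df.at[idx, 'Age']}.5"
            truth[normalize_labid(df.at[idx, "LabID"])].update(
                kept=False, reasons=[reason.name],
                final_lon=None, final_lat=None)

    for idx in take(spec.corrupt_text):
        old = df.at[idx, "LabID"]
        df.at[idx, "LabID"] = old + "√•"
        truth.pop(normalize_labid(old))
        truth[normalize_labid(df.at[idx, "LabID"])] = {
            "kept": False, "reasons": [Reason.CORRUPT_LABID.name],
            "final_lon": None, "final_lat": None, "final_source": None}

    for idx in take(spec.mask_targets):
        df.at[idx, "Country"] = "USA"
        lon, lat = float(df.at[idx, "Long"]), float(df.at[idx, "Lat"])
        cx, cy = assign_admin((lon, lat), mask_layer).centroid
        t = truth[normalize_labid(df.at[idx, "LabID"])]
        t["final_lon"], t["final_lat"] = cx, cy

    if appended:
        df = pd.concat([df, pd.DataFrame(appended)], ignore_index=True)

    truth_df = pd.DataFrame(
        [{"lab_id": k, "kept": v["kept"],
          "reasons": "|".join(sorted(v["reasons"])),
          "final_lon": v["final_lon"], "final_lat": v["final_lat"],
          "final_source": v["final_source"] or ""}
         for k, v in truth.items()]
    )
    return RecordTable(df, provenance=list(table.provenance)), truth_df


def check_truth(truth: pd.DataFrame, scrubbed: RecordTable,
                graveyard: pd.DataFrame, coord_tol: float = 1e-6) -> list:
    """Compare a pipeline outcome against a truth log.

    Returns a list of human-readable mismatch descriptions (empty on a
    perfect, record-level match of fates, graveyard reasons, final
    coordinates and merged sources).
    """
    problems = []
    kept_by_id = {}
    for rec in scrubbed.df.to_dict("records"):
        kept_by_id.setdefault(normalize_labid(rec["LabID"]), []).append(rec)
    grave_by_id: dict = {}
    if len(graveyard):
        for rec in graveyard.to_dict("records"):
            grave_by_id.setdefault(normalize_labid(rec["LabID"]), []).append(rec["reason"])

    for t in truth.to_dict("records"):
        lid = t["lab_id"]
        kept = kept_by_id.get(lid, [])
        reasons = "|".join(sorted(grave_by_id.get(lid, [])))
        if t["kept"] != (len(kept) == 1):
            problems.append(f"{lid}: expected kept={t['kept']}, found {len(kept)}")
            continue
        if reasons != t["reasons"]:
            problems.append(f"{lid}: reasons {reasons!r} != {t['reasons']!r}")
        if t["kept"]:
            rec = kept[0]
            lon, lat = parse_float(rec["Long"]), parse_float(rec["Lat"])
            for got, want, axis in ((lon, t["final_lon"], "lon"),
                                    (lat, t["final_lat"], "lat")):
                want = None if pd.isna(want) else want
                if (want is None) != (got is None) or (
                        want is not None and abs(got - want) > coord_tol):
                    problems.append(f"{lid}: final {axis} {got} != {want}")
            if t["final_source"] and rec["Source"] != t["final_source"]:
                problems.append(f"{lid}: source {rec['Source']!r} != "
                                f"{t['final_source']!r}")
    extra = set(kept_by_id) - set(truth["lab_id"])
    if extra:
        problems.append(f"unexpected surviving lab ids: {sorted(extra)[:5]}")
    return problems


def generate_clustered_sites(k: int, sites_per_cluster: int, weights,
                             seed: int, centers=None, spread: float = 0.5):
    """Gaussian site clusters with per-cluster date weights.

    ``weights`` is one number per cluster (dates per site in that
    cluster). Returns ``(points, point_weights)``.
    """
    if k < 1:
        raise ValueError("need at least one cluster")
    rng = np.random.default_rng(seed)
    if centers is None:
        centers = [(5.0 * i, 0.0) for i in range(k)]
    weights = list(weights)
    if len(weights) != k:
        raise ValueError("need one weight per cluster")
    pts, w = [], []
    for ci in range(k):
        c = centers[ci]
        pts.append(rng.normal(loc=c, scale=spread, size=(sites_per_cluster, 2)))
        w.extend([float(weights[ci])] * sites_per_cluster)
    return np.vstack(pts), np.asarray(w)


def generate_loglog_units(n: int, slope: float, seed: int,
                          intercept: float = 0.5, x_sd: float = 0.5,
                          noise_sd: float = 0.1) -> pd.DataFrame:
    """Synthetic per-unit densities with a known log-log generative slope.

    log10 date density = intercept + slope * log10 site density + noise.
    """
    rng = np.random.default_rng(seed)
    lx = rng.normal(0.0, x_sd, n)
    ly = intercept + slope * lx + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame({"unit": [f"u{i}" for i in range(n)],
                         "site_density": 10.0 ** lx,
                         "date_density": 10.0 ** ly})
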