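"""Record schema, delimited-text I/O, and string sanitation.

The canonical table layout is the harmonized radiocarbon-record schema used
by synthetic global compilations: one row per dated sample, identified by a
laboratory number (``LabID``), with an uncalibrated age and one-sigma error
in radiocarbon years BP, optional isotopic/material metadata, coordinates in
decimal degrees, an ordinal location-accuracy grade, and provenance fields.

All cells are carried as text. Numeric interpretation happens in the
pipeline stages that need it (and that delete offending records); nothing is
silently coerced at read time. Output is always UTF-8 — falling back to a
locale encoding is precisely the failure mode that corrupts site names in
the wild, so the writer never does it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

#: Canonical column order of the harmonized schema.
COLUMNS = [
    "LabID", "Age", "Error", "Material", "Taxa", "d13C", "Method", "Period",
    "SiteID", "SiteName", "Long", "Lat", "LocAccuracy", "Country",
    "Province", "Region", "Continent", "Source", "Reference",
]

#: Columns that must be present (possibly blank-valued) in any input table.
REQUIRED_COLUMNS = ["LabID", "Age", "Error", "LocAccuracy", "Continent", "Source"]

#: Columns holding numeric-ish content; exempt from string sanitation.
NUMERIC_COLUMNS = {"Age", "Error", "d13C", "LocAccuracy", "Lat", "Long"}

#: Header aliases, case-insensitive, versioned with the package.
HEADER_ALIASES = {
    "labid": "LabID", "lab_id": "LabID", "labnumber": "LabID",
    "lab_number": "LabID", "labno": "LabID",
    "age": "Age", "c14age": "Age", "bp": "Age",
    "error": "Error", "sd": "Error", "sigma": "Error", "std": "Error",
    "material": "Material", "taxa": "Taxa", "taxon": "Taxa",
    "d13c": "d13C", "delta13c": "d13C", "dc13": "d13C",
    "method": "Method", "period": "Period",
    "siteid": "SiteID", "site_id": "SiteID",
    "sitename": "SiteName", "site_name": "SiteName", "site": "SiteName",
    "long": "Long", "lon": "Long", "longitude": "Long", "lng": "Long",
    "lat": "Lat", "latitude": "Lat",
    "locaccuracy": "LocAccuracy", "loc_accuracy": "LocAccuracy",
    "country": "Country", "province": "Province", "state": "Province",
    "region": "Region", "continent": "Continent",
    "source": "Source", "reference": "Reference", "ref": "Reference",
}

#: Characters stripped from free-text fields: straight and typographic
#: quotation marks plus commas (CSV-hostile characters).
_SANITIZE_RE = re.compile("[\"'‘’‚‛“”„«»‹›,]")
_WS_RE = re.compile(r"\s+")


class SchemaError(ValueError):
    """Raised when an input table lacks required columns."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"missing required column(s): {', '.join(self.missing)}")


class Reason(str, Enum):
    """Machine-groupable removal-reason codes for the graveyard."""

    UNKNOWN_LAB = "unknown lab code"
    AGE_MISMATCH = "age mismatch"
    TRUE_DUPLICATE = "true duplicate"
    DUPLICATE_SUPERSEDED = "duplicate superseded"
    LOCATION_CONFLICT = "location conflict"
    MISSING_AGE = "missing age"
    NON_INTEGER_AGE = "non-integer age"
    NONPOSITIVE_AGE = "nonpositive age"
    MISSING_ERROR = "missing error"
    NON_INTEGER_ERROR = "non-integer error"
    ERROR_TOO_SMALL = "error below minimum"
    ERROR_EXCEEDS_AGE = "error larger than age"
    AGE_TOO_OLD = "age beyond calibration limit"
    CORRUPT_LABID = "corrupted lab id"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class GraveyardEntry:
    """A removed record, its removal reason, and the pipeline stage."""

    record: dict
    reason: Reason
    stage: str


@dataclass
class RecordTable:
    """A record table plus the provenance of the file(s) it came from.

    Thin wrapper around a :class:`pandas.DataFrame` whose cells are all
    strings in the canonical column order (extra columns preserved at the
    end).
    """

    df: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)


def _canonical_name(header: str):
    return HEADER_ALIASES.get(header.strip().lower())


def read_records(path, sep: str = ",", encoding: str = "utf-8") -> RecordTable:
    """Read a delimited table into the canonical schema.

    Headers are matched case-insensitively through the documented alias
    table; unknown extra columns are preserved untouched. Undecodable bytes
    are replaced with U+FFFD (which the corrupt-text detector flags
    downstream) rather than raising.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False,
                     encoding=encoding, encoding_errors="replace")
    rename = {}
    for col in df.columns:
        canon = _canonical_name(str(col))
        if canon is not None and canon not in rename.values():
            rename[col] = canon
    df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(missing)
    for c in COLUMNS:
        if c not in df.columns:
            df[c] = ""
    extras = [c for c in df.columns if c not in COLUMNS]
    df = df[COLUMNS + extras].reset_index(drop=True)
    return RecordTable(df, provenance=[str(path)])


def sanitize_strings(table: RecordTable) -> RecordTable:
    """Strip quotation marks and commas from free-text fields.

    Numeric-ish fields (ages, errors, coordinates, δ13C, LocAccuracy) are
    left untouched — coordinate strings legitimately contain minute/second
    marks until the standardization stage parses them. Whitespace runs left
    behind by the removals are collapsed.
    """
    df = table.df.copy()
    for col in df.columns:
        if col in NUMERIC_COLUMNS:
            continue
        cleaned = df[col].str.replace(_SANITIZE_RE, "", regex=True)
        df[col] = cleaned.str.replace(_WS_RE, " ", regex=True).str.strip()
    return RecordTable(df, provenance=list(table.provenance))


def write_records(table: RecordTable, path) -> None:
    """Write the table as UTF-8 CSV in canonical column order."""
    extras = [c for c in table.df.columns if c not in COLUMNS]
    out = table.df[COLUMNS + extras]
    out.to_csv(path, index=False, encoding="utf-8")


def graveyard_frame(entries) -> pd.DataFrame:
    """Assemble graveyard entries into a writable frame.

    Columns are the record columns plus ``reason`` (machine code),
    ``reason_detail`` (human text) and ``stage``.
    """
    rows = []
    for e in entries:
        row = {c: e.record.get(c, "") for c in COLUMNS}
        row["reason"] = e.reason.name
        row["reason_detail"] = e.reason.value
        row["stage"] = e.stage
        rows.append(row)
    cols = COLUMNS + ["reason", "reason_detail", "stage"]
    return pd.DataFrame(rows, columns=cols, dtype=str)


def write_graveyard(entries, path) -> None:
    graveyard_frame(entries).to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# numeric helpers shared by the cleaning stages

def is_blank(s) -> bool:
    return s is None or str(s).strip() == ""


def parse_float(s):
    """Float value of a cell, or None if blank/unparseable."""
    if is_blank(s):
        return None
    try:
        return float(str(s).strip())
    except ValueError:
        return None


def parse_int(s):
    """Integer value of a cell; integral floats ("1050.0") count as integers.

    Returns None for blank cells and raises nothing: the caller decides the
    fate of non-integer content.
    """
    if is_blank(s):
        return None
    t = str(s).strip()
    try:
        return int(t)
    except ValueError:
        pass
    try:
        v = float(t)
    except ValueError:
        return None
    if v == int(v):
        return int(v)
    return None
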