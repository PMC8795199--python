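"""Laboratory-code validation (cleaning step 1).

Every radiocarbon measurement carries a lab number such as ``OxA-1234`` or
``Beta 287941``; the leading alphabetic token identifies the dating
laboratory. Records whose code does not resolve against a registry of known
laboratories are expunged — an unrecognizable code means the measurement's
origin cannot be verified.

The shipped registry (400+ prefixes with laboratory name and country) is a
reconstruction from published laboratory-code conventions and is
user-replaceable; laboratories open, close and rename.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .records import GraveyardEntry, Reason, RecordTable

_STAGE = "labcodes"


@dataclass
class LabCodeRegistry:
    """Mapping of case-normalized code prefix -> (laboratory name, country)."""

    entries: dict = field(default_factory=dict)

    def __post_init__(self):
        self.entries = {str(k).strip().upper(): tuple(v) for k, v in self.entries.items()}
        if not self.entries:
            raise ValueError("registry must be non-empty")

    def __contains__(self, code) -> bool:
        return code is not None and str(code).upper() in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, code):
        return self.entries.get(str(code).upper())

    @classmethod
    def from_csv(cls, path) -> "LabCodeRegistry":
        """Load a registry CSV with columns code,lab_name,country."""
        entries = {}
        with open(path, encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                entries[row["code"]] = (row.get("lab_name", ""), row.get("country", ""))
        return cls(entries)

    @classmethod
    def bundled(cls) -> "LabCodeRegistry":
        """The registry shipped with the package."""
        ref = resources.files("c14scrub.data") / "labcodes.csv"
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


def extract_lab_code(lab_id):
    """Leading alphabetic token of a lab number, case-normalized.

    Letters before the first digit, hyphen, space, slash, or any other
    non-letter character. ``None`` when the lab number has no leading
    alphabetic token (e.g. a bare number).
    """
    s = str(lab_id).strip()
    out = []
    for ch in s:
        if ch.isalpha():
            out.append(ch)
        else:
            break
    if not out:
        return None
    return "".join(out).upper()


def purge_unknown_labs(table: RecordTable, registry: LabCodeRegistry):
    """Split a table into records with registered lab codes and a graveyard.

    Order of kept records is preserved; a record without an extractable
    alphabetic prefix is treated as unknown.
    """
    keep_mask = []
    removed = []
    for rec in table.df.to_dict("records"):
        code = extract_lab_code(rec.get("LabID", ""))
        ok = code in registry
        keep_mask.append(ok)
        if not ok:
            removed.append(GraveyardEntry(rec, Reason.UNKNOWN_LAB, _STAGE))
    kept = table.df[pd.Series(keep_mask, index=table.df.index)].reset_index(drop=True)
    return RecordTable(kept, provenance=list(table.provenance)), removed
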