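"""Miscellaneous anomaly filtering (cleaning step 4).

Rule-explicit chronometric hygiene: records are deleted when their age is
missing, non-integer (radiocarbon measurement cannot resolve sub-year
ages), zero or negative ("dates from the future"), beyond the calibration
curve limit, or when their one-sigma error is missing, non-integer,
implausibly small, or larger than the age itself. Lab numbers containing
mojibake are also removed — a corrupted identifier cannot be cross-checked
against anything.

Rules are evaluated in a fixed order and the first failing rule names the
removal reason, so graveyard counts are exactly attributable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .records import (GraveyardEntry, Reason, RecordTable, is_blank,
                      parse_float)

_STAGE = "filters"


@dataclass(frozen=True)
class FilterConfig:
    """Bounds of the anomaly rules, in radiocarbon years.

    ``min_error_yr`` — smallest credible one-sigma error (15 yr by
    default; smaller values overstate measurement precision).
    ``max_age_bp`` — oldest age the calibration curve can handle
    (55,000 BP by default). Boundary readings are literal: an error of
    exactly ``min_error_yr``, an error equal to the age, and an age of
    exactly ``max_age_bp`` are all kept.
    """

    min_error_yr: int = 15
    max_age_bp: int = 55_000

    def __post_init__(self):
        if self.min_error_yr < 1:
            raise ValueError("min_error_yr must be >= 1")
        if self.max_age_bp <= self.min_error_yr:
            raise ValueError("max_age_bp must exceed min_error_yr")


def _load_default_patterns():
    ref = resources.files("c14scrub.data") / "mojibake_patterns.txt"
    pats = []
    for line in ref.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            pats.append(re.compile(line))
    return pats


_DEFAULT_PATTERNS = None


def mojibake_patterns():
    """The compiled mojibake pattern set (data-driven, editable)."""
    global _DEFAULT_PATTERNS
    if _DEFAULT_PATTERNS is None:
        _DEFAULT_PATTERNS = _load_default_patterns()
    return _DEFAULT_PATTERNS


def has_corrupt_text(s, patterns=None):
    """Detect mojibake in a string.

    Returns ``(flag, spans)`` where spans are the offending substrings. The
    pattern set covers the replacement character and the Ã/√/â sequences
    produced by decoding UTF-8 bytes as a legacy single-byte encoding.
    """
    patterns = patterns if patterns is not None else mojibake_patterns()
    text = str(s)
    spans = []
    for pat in patterns:
        spans.extend(m.group(0) for m in pat.finditer(text))
    return bool(spans), spans


def _integer_of(cell):
    """(value, status) where status in {"ok", "missing", "non-integer"}."""
    if is_blank(cell):
        return None, "missing"
    v = parse_float(cell)
    if v is None or v != int(v):
        return None, "non-integer"
    return int(v), "ok"


def _first_failure(rec, cfg: FilterConfig):
    """The first rule the record violates, or None if it survives."""
    age, age_status = _integer_of(rec.get("Age"))
    if age_status == "missing":
        return Reason.MISSING_AGE
    if age_status == "non-integer":
        return Reason.NON_INTEGER_AGE
    if age <= 0:
        return Reason.NONPOSITIVE_AGE
    err, err_status = _integer_of(rec.get("Error"))
    if err_status == "missing":
        return Reason.MISSING_ERROR
    if err_status == "non-integer":
        return Reason.NON_INTEGER_ERROR
    if err < cfg.min_error_yr:
        return Reason.ERROR_TOO_SMALL
    if err > age:
        return Reason.ERROR_EXCEEDS_AGE
    if age > cfg.max_age_bp:
        return Reason.AGE_TOO_OLD
    if has_corrupt_text(rec.get("LabID", ""))[0]:
        return Reason.CORRUPT_LABID
    return None


def apply_filters(table: RecordTable, cfg: FilterConfig | None = None):
    """Apply the anomaly rules; route every removal to the graveyard.

    Kept records keep their input order, and their Age/Error cells are
    normalized to canonical integer text (e.g. "1050.0" -> "1050").
    """
    cfg = cfg or FilterConfig()
    kept_rows, removed = [], []
    for rec in table.df.to_dict("records"):
        reason = _first_failure(rec, cfg)
        if reason is None:
            rec["Age"] = str(_integer_of(rec["Age"])[0])
            rec["Error"] = str(_integer_of(rec["Error"])[0])
            kept_rows.append(rec)
        else:
            removed.append(GraveyardEntry(rec, reason, _STAGE))
    cols = list(table.df.columns)
    kept = pd.DataFrame(kept_rows, columns=cols, dtype=str)
    return RecordTable(kept, provenance=list(table.provenance)), removed
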