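"""Duplicate-record resolution (cleaning step 3).

Two records are duplicates when they bear the same laboratory number: a
physical sample is measured once, so multiple rows with one LabID are the
same measurement reported through different compilations. The resolution
cascade, applied per LabID group and in this order:

1. If the group's ages (or errors) disagree, the true measurement is
   unrecoverable — every instance is deleted (reason "age mismatch").
2. Identical age and identical location: true duplicates. One is kept and
   the source names of all instances are concatenated into its Source.
3. A member from a higher-priority source supersedes the others (systematic
   collection efforts are trusted over voluntary-submission databases).
4. Otherwise the member with the highest LocAccuracy wins.
5. Remaining ties are broken by δ13C plausibility rank.
6. Members still tied but with coordinates differing by more than the
   ±fuzz-factor in either axis are an unresolvable location conflict —
   every instance is deleted.

The cascade's residual "arbitrary" choice is made reproducible:
lexicographically smallest source name, then first input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .records import (GraveyardEntry, Reason, RecordTable, is_blank,
                      parse_float)

_STAGE = "dedup"
SOURCE_SEP = "; "


@dataclass(frozen=True)
class DedupPolicy:
    """Tunables of the duplicate cascade.

    ``source_priority`` lists source names from most to least trusted;
    unlisted sources rank equally below all listed ones. ``fuzz_deg`` is the
    acceptable per-axis coordinate dissimilarity between instances of one
    record; ``d13c_band`` the plausible per-mil interval for first-priority
    δ13C values.
    """

    source_priority: tuple = ("UWyo2021", "CARD")
    fuzz_deg: float = 0.5
    d13c_band: tuple = (-30.0, -1.0)

    def __post_init__(self):
        if self.fuzz_deg <= 0:
            raise ValueError("fuzz_deg must be positive")
        if not self.d13c_band[0] < self.d13c_band[1]:
            raise ValueError("d13c_band lower bound must be below upper")

    def source_rank(self, source) -> int:
        s = str(source).strip()
        try:
            return self.source_priority.index(s)
        except ValueError:
            return len(self.source_priority)


def normalize_labid(lab_id) -> str:
    """Case- and whitespace-insensitive LabID key."""
    return "".join(str(lab_id).split()).casefold()


def group_by_labid(table) -> dict:
    """Exhaustive, disjoint grouping of rows by normalized LabID.

    Accepts a RecordTable or DataFrame; returns key -> list of row dicts
    (each carrying its original position under ``"_idx"``), keys in first-
    appearance order.
    """
    df = table.df if isinstance(table, RecordTable) else table
    groups: dict = {}
    for idx, rec in enumerate(df.to_dict("records")):
        rec["_idx"] = idx
        groups.setdefault(normalize_labid(rec.get("LabID", "")), []).append(rec)
    return groups


def d13c_rank(value, band=(-30.0, -1.0)) -> int:
    """Plausibility rank of a δ13C cell: 1 best, 4 worst.

    1: within the plausible band; 2: present, nonzero, outside the band;
    3: present and exactly zero (many compilations used 0 for "missing");
    4: absent or unparseable.
    """
    v = value if isinstance(value, (int, float)) else parse_float(value)
    if v is None:
        return 4
    if band[0] <= v <= band[1]:
        return 1
    if v == 0:
        return 3
    return 2


def _age_key(rec):
    """Comparable (age, error) pair; numeric when parseable, text otherwise."""
    out = []
    for col in ("Age", "Error"):
        v = parse_float(rec.get(col))
        out.append(v if v is not None else str(rec.get(col, "")).strip())
    return tuple(out)


def _loc_key(rec):
    """Location identity: coordinates rounded to 4 decimals, or absent."""
    lon, lat = parse_float(rec.get("Long")), parse_float(rec.get("Lat"))
    if lon is None or lat is None:
        return None
    return (round(lon, 4), round(lat, 4))


def _loc_accuracy(rec) -> int:
    v = parse_float(rec.get("LocAccuracy"))
    return int(v) if v is not None else -1


def _tiebreak_key(rec):
    return (str(rec.get("Source", "")).strip(), rec["_idx"])


def _merge_sources(members) -> str:
    # sorted so the merge is independent of input row order
    seen = set()
    for m in members:
        for s in str(m.get("Source", "")).split(SOURCE_SEP.strip()):
            if s.strip():
                seen.add(s.strip())
    return SOURCE_SEP.join(sorted(seen))


def resolve_group(members, policy: DedupPolicy | None = None):
    """Resolve one LabID group.

    Returns ``(kept, removed)`` where ``kept`` is a single record dict or
    ``None`` and ``removed`` a list of GraveyardEntry. Singleton groups pass
    through untouched.
    """
    policy = policy or DedupPolicy()
    if len(members) == 1:
        return members[0], []

    # (1) conflicting measurements: the age cannot be trusted
    if len({_age_key(m) for m in members}) > 1:
        return None, [GraveyardEntry(m, Reason.AGE_MISMATCH, _STAGE) for m in members]

    # (2) identical age + identical location: true duplicates, merge sources
    if len({_loc_key(m) for m in members}) == 1:
        winner = min(members, key=lambda m: (
            policy.source_rank(m.get("Source")),
            -_loc_accuracy(m),
            d13c_rank(m.get("d13C"), policy.d13c_band),
            _tiebreak_key(m),
        ))
        winner = dict(winner)
        winner["Source"] = _merge_sources(members)
        removed = [GraveyardEntry(m, Reason.TRUE_DUPLICATE, _STAGE)
                   for m in members if m["_idx"] != winner["_idx"]]
        return winner, removed

    # (3)–(5) successive narrowing of the candidate set
    cands = list(members)
    for key in (
        lambda m: policy.source_rank(m.get("Source")),
        lambda m: -_loc_accuracy(m),
        lambda m: d13c_rank(m.get("d13C"), policy.d13c_band),
    ):
        best = min(key(m) for m in cands)
        cands = [m for m in cands if key(m) == best]
        if len(cands) == 1:
            break

    if len(cands) > 1:
        # (6) still tied (hence equal LocAccuracy): instances whose
        # coordinates disagree beyond the fuzz factor are unresolvable
        locs = [_loc_key(m) for m in cands]
        present = [l for l in locs if l is not None]
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                if (abs(present[i][0] - present[j][0]) > policy.fuzz_deg
                        or abs(present[i][1] - present[j][1]) > policy.fuzz_deg):
                    return None, [GraveyardEntry(m, Reason.LOCATION_CONFLICT, _STAGE)
                                  for m in members]

    winner = min(cands, key=_tiebreak_key)
    removed = [GraveyardEntry(m, Reason.DUPLICATE_SUPERSEDED, _STAGE)
               for m in members if m["_idx"] != winner["_idx"]]
    return winner, removed


def dedup_table(table: RecordTable, policy: DedupPolicy | None = None):
    """Resolve every duplicate group of a table.

    Kept records appear in the order their winner first appeared in the
    input; output LabIDs are unique (after normalization).
    """
    policy = policy or DedupPolicy()
    kept_rows, removed = [], []
    for members in group_by_labid(table).values():
        winner, gone = resolve_group(members, policy)
        if winner is not None:
            kept_rows.append(winner)
        removed.extend(gone)
    kept_rows.sort(key=lambda m: m["_idx"])
    cols = list(table.df.columns)
    kept = pd.DataFrame([{c: r.get(c, "") for c in cols} for r in kept_rows],
                        columns=cols, dtype=str)
    for e in removed:
        e.record.pop("_idx", None)
    return RecordTable(kept, provenance=list(table.provenance)), removed
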