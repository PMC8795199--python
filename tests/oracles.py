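"""Independent reference implementations used as test oracles.

Each oracle is a direct, unoptimized transcription of the documented rules,
kept structurally separate from the package code it checks.
"""

import numpy as np


# --- duplicate-cascade oracle (pairwise, explicit ifs) ---------------------

def oracle_resolve(members, source_priority=("UWyo2021", "CARD"), fuzz=0.5):
    """Expected outcome for one duplicate group.

    ``members`` are dicts with keys: idx, age, error, la, d13c, lon, lat,
    source (lon/lat may be None). Returns (kept_idx_or_None, reason_by_idx).
    """
    if len(members) == 1:
        return members[0]["idx"], {}

    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            if (members[i]["age"] != members[j]["age"]
                    or members[i]["error"] != members[j]["error"]):
                return None, {m["idx"]: "AGE_MISMATCH" for m in members}

    def loc(m):
        if m["lon"] is None or m["lat"] is None:
            return None
        return (round(m["lon"], 4), round(m["lat"], 4))

    def srank(m):
        return (source_priority.index(m["source"])
                if m["source"] in source_priority else len(source_priority))

    def better(a, b):
        """True when a beats b in the priority comparator."""
        if srank(a) != srank(b):
            return srank(a) < srank(b)
        if a["la"] != b["la"]:
            return a["la"] > b["la"]
        if a["d13c_rank"] != b["d13c_rank"]:
            return a["d13c_rank"] < b["d13c_rank"]
        if a["source"] != b["source"]:
            return a["source"] < b["source"]
        return a["idx"] < b["idx"]

    def best_of(group):
        w = group[0]
        for m in group[1:]:
            if better(m, w):
                w = m
        return w

    if len({loc(m) for m in members}) == 1:
        winner = best_of(members)
        return winner["idx"], {m["idx"]: "TRUE_DUPLICATE" for m in members
                               if m["idx"] != winner["idx"]}

    cands = [m for m in members if srank(m) == min(srank(x) for x in members)]
    if len(cands) > 1:
        cands = [m for m in cands if m["la"] == max(x["la"] for x in cands)]
    if len(cands) > 1:
        cands = [m for m in cands
                 if m["d13c_rank"] == min(x["d13c_rank"] for x in cands)]
    if len(cands) > 1:
        with_loc = [m for m in cands if loc(m) is not None]
        for i in range(len(with_loc)):
            for j in range(i + 1, len(with_loc)):
                a, b = loc(with_loc[i]), loc(with_loc[j])
                if abs(a[0] - b[0]) > fuzz or abs(a[1] - b[1]) > fuzz:
                    return None, {m["idx"]: "LOCATION_CONFLICT" for m in members}
    winner = best_of(cands)
    return winner["idx"], {m["idx"]: "DUPLICATE_SUPERSEDED" for m in members
                           if m["idx"] != winner["idx"]}


# --- edit-distance oracle (recursive definition with memoization) ----------

def oracle_dl(a: str, b: str) -> int:
    """Restricted Damerau–Levenshtein straight from the recurrence."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def d(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        best = min(d(i - 1, j) + 1, d(i, j - 1) + 1,
                   d(i - 1, j - 1) + (a[i - 1] != b[j - 1]))
        if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
            best = min(best, d(i - 2, j - 2) + 1)
        return best

    import sys
    old = sys.getrecursionlimit()
    sys.setrecursionlimit(10000)
    try:
        return d(len(a), len(b))
    finally:
        sys.setrecursionlimit(old)


# --- brute-force KDE (double loop) -----------------------------------------

def oracle_kde(points, weights, hx, hy, gx, gy):
    z = np.zeros((len(gy), len(gx)))
    for j, yv in enumerate(gy):
        for i, xv in enumerate(gx):
            total = 0.0
            for (px, py), w in zip(points, weights):
                total += w * np.exp(-0.5 * ((xv - px) / hx) ** 2
                                    - 0.5 * ((yv - py) / hy) ** 2) / (
                    2 * np.pi * hx * hy)
            z[j, i] = total
    return z
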