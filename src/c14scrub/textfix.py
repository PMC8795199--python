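"""Assisted repair of encoding anomalies in site names.

Site names with characters outside basic Latin get garbled when a dataset
is round-tripped through a legacy single-byte encoding ("Barkåker" becomes
"Bark√•ker", "Alsónémedi" becomes "AlsÃ³nÃ©medi"). The corruption corpus in
real compilations is too diverse for fully automatic repair, so this module
implements the assisted workflow: build a corpus of uncorrupted tokens
(from the tables themselves plus a gazetteer word list), flag corrupt
tokens, and rank candidate corrections within a bounded edit distance.
A human — or a scripted answer file, for reproducible runs — makes the
final call. Material and Reference fields are only ever flagged, never
auto-fixed: their content cannot be inferred from the rest of the record.

Edit distance is restricted Damerau–Levenshtein (substitution, insertion,
deletion, and adjacent transposition all cost 1), the metric spell-checking
engines conventionally use.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .filters import has_corrupt_text
from .records import RecordTable

#: tokens are runs of word characters (unicode letters/digits) plus
#: non-ASCII symbols, so mojibake glyphs stay inside their token
_TOKEN_RE = re.compile(r"[^\s,;:()\[\]/\\]+")

DEFAULT_MAX_DIST = 5


@dataclass
class CorrectionCorpus:
    """Multiset of uncorrupted tokens with frequencies."""

    words: Counter = field(default_factory=Counter)

    def __len__(self):
        return len(self.words)


@dataclass(frozen=True)
class Suggestion:
    candidate: str
    edit_distance: int
    frequency: int


def tokenize(text) -> list:
    return _TOKEN_RE.findall(str(text))


def build_corpus(tables, gazetteer=(), text_columns=("SiteName", "SiteID",
                                                     "Country", "Province",
                                                     "Region")) -> CorrectionCorpus:
    """Accumulate uncorrupted tokens from record tables plus a gazetteer.

    Corrupt tokens (per the mojibake pattern set) are excluded, so the
    corpus can never suggest a corruption as a correction.
    """
    words: Counter = Counter()
    for table in tables:
        df = table.df if isinstance(table, RecordTable) else table
        for col in text_columns:
            if col not in df.columns:
                continue
            for cell in df[col]:
                for tok in tokenize(cell):
                    if not has_corrupt_text(tok)[0]:
                        words[tok] += 1
    for w in gazetteer:
        w = str(w).strip()
        if w and not has_corrupt_text(w)[0]:
            words[w] += 1
    return CorrectionCorpus(words)


def damerau_levenshtein(a: str, b: str, cap: int | None = None) -> int:
    """Restricted Damerau–Levenshtein distance (optimal string alignment).

    ``cap`` allows early abandon: once every entry of a row exceeds it the
    true distance is known to exceed it and ``cap + 1`` is returned.
    """
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if cap is not None and abs(la - lb) > cap:
        return cap + 1
    prev2: list = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (i > 1 and j > 1 and a[i - 1] == b[j - 2]
                    and a[i - 2] == b[j - 1]):
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        if cap is not None and min(cur) > cap:
            return cap + 1
        prev2, prev = prev, cur
    return prev[lb]


def suggest(word: str, corpus: CorrectionCorpus,
            max_dist: int = DEFAULT_MAX_DIST) -> list:
    """Ranked corrections for a corrupt token.

    All corpus words within the distance bound, ordered by (distance
    ascending, frequency descending, lexicographic). Raises ``ValueError``
    when the input token is not actually flagged as corrupt — suggesting
    "fixes" for clean text is how good names get clobbered.
    """
    if not has_corrupt_text(word)[0]:
        raise ValueError(f"token {word!r} is not flagged as corrupt")
    out = []
    for cand, freq in corpus.words.items():
        d = damerau_levenshtein(word, cand, cap=max_dist)
        if d <= max_dist:
            out.append(Suggestion(cand, d, freq))
    out.sort(key=lambda s: (s.edit_distance, -s.frequency, s.candidate))
    return out


def parse_answer_file(path) -> dict:
    """Answer file: one tab-separated ``token<TAB>decision`` per line.

    Decision is ``accept`` (take the top suggestion), ``skip``, or a
    literal replacement token. Lines starting with ``#`` are comments.
    """
    answers = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            token, _, decision = line.partition("\t")
            answers[token] = decision.strip() or "skip"
    return answers


def interactive_fix(table: RecordTable, corpus: CorrectionCorpus,
                    answers: dict | None = None, max_dist: int = DEFAULT_MAX_DIST,
                    prompt=None):
    """Resolve every flagged SiteName token of a table.

    ``answers`` maps corrupt tokens to decisions (see
    :func:`parse_answer_file`); ``prompt`` is an optional callable
    ``(token, context, suggestions) -> decision`` for live sessions. With
    neither, a table containing corruptions aborts with the unresolved
    count. Returns the fixed table and a change log (one row per flagged
    token occurrence: site, token, decision, replacement).
    """
    df = table.df.copy()
    logrows = []
    unresolved = 0
    for idx, name in zip(df.index, df["SiteName"]):
        if not has_corrupt_text(name)[0]:
            continue
        new_name = str(name)
        for tok in tokenize(name):
            if not has_corrupt_text(tok)[0]:
                continue
            sugg = suggest(tok, corpus, max_dist)
            if answers is not None and tok in answers:
                decision = answers[tok]
            elif prompt is not None:
                decision = prompt(tok, name, sugg)
            else:
                unresolved += 1
                continue
            if decision == "skip":
                replacement = None
            elif decision == "accept":
                replacement = sugg[0].candidate if sugg else None
            else:
                replacement = decision
            if replacement is not None:
                new_name = new_name.replace(tok, replacement)
            logrows.append({"row": idx, "site_name": str(name), "token": tok,
                            "decision": decision,
                            "replacement": replacement or ""})
        df.at[idx, "SiteName"] = new_name
    if unresolved:
        raise RuntimeError(f"{unresolved} corrupt token(s) left unresolved: "
                           "no answer file and no interactive session")
    changelog = pd.DataFrame(logrows, columns=["row", "site_name", "token",
                                               "decision", "replacement"])
    return RecordTable(df, provenance=list(table.provenance)), changelog
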