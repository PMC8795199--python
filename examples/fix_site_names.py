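"""Repair encoding-corrupted site names with a scripted answer file.

"Barkåker" round-tripped through a legacy encoding becomes "Bark√•ker".
The corpus of uncorrupted tokens (from the tables themselves plus a
gazetteer) supplies ranked candidate corrections within edit distance 5;
an answer file makes the human decisions reproducible.
"""

import c14scrub as c
from c14scrub.records import COLUMNS, RecordTable
import pandas as pd

rows = [
    {"LabID": "T-1", "SiteName": "Bark√•ker"},      # corrupted
    {"LabID": "T-2", "SiteName": "Barkåker"},       # clean occurrence
    {"LabID": "T-3", "SiteName": "AlsÃ³nÃ©medi"},   # corrupted
]
table = RecordTable(pd.DataFrame(
    [{**{col: "" for col in COLUMNS}, **r} for r in rows],
    columns=COLUMNS, dtype=str))

corpus = c.build_corpus([table], gazetteer=["Alsónémedi", "Vindheim"])
for corrupt in ("Bark√•ker", "AlsÃ³nÃ©medi"):
    top = c.suggest(corrupt, corpus)[0]
    print(f"{corrupt!r} -> top suggestion {top.candidate!r} "
          f"(edit distance {top.edit_distance})")

fixed, changelog = c.interactive_fix(
    table, corpus, answers={"Bark√•ker": "accept", "AlsÃ³nÃ©medi": "accept"})
print("repaired site names:", list(fixed.df["SiteName"]))
print(changelog.to_string(index=False))
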