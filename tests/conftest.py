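import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from c14scrub import LabCodeRegistry, RecordTable
from c14scrub.records import COLUMNS
from c14scrub.synth import generate_admin_grid


def make_table(rows) -> RecordTable:
    """Build a RecordTable from partial row dicts (missing cells blank)."""
    full = [{**{c: "" for c in COLUMNS}, **r} for r in rows]
    df = pd.DataFrame(full, columns=COLUMNS, dtype=str) if full else \
        pd.DataFrame(columns=COLUMNS, dtype=str)
    return RecordTable(df)


def record(**kw) -> dict:
    """One full record dict with blanks for unspecified columns."""
    base = {c: "" for c in COLUMNS}
    base.update(kw)
    return base


@pytest.fixture
def toy_registry():
    return LabCodeRegistry({"OXA": ("Oxford", "UK"),
                            "BETA": ("Beta Analytic", "USA"),
                            "AECV": ("Vegreville", "Canada")})


@pytest.fixture
def unit_grid():
    """A 4x4 grid of 1-degree admin cells covering (0,0)-(4,4)."""
    return generate_admin_grid(4, 4, 1.0)
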