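"""Orchestration of the scrubbing stages in their fixed order.

The sequence mirrors the five-step cleaning protocol for heterogeneous
radiocarbon compilations: string sanitation, lab-code purging, coordinate
standardization (with optional location verification against boundary
polygons — opt-in, because it changes record counts and the published
protocol ran it as a supervised phase), duplicate resolution, anomaly
filtering, and coordinate obfuscation for protected subsets.

Every removal is routed to the graveyard with a reason and stage; the run
report carries per-stage kept/removed counts and a reason histogram, and
the conservation identity |input| = |output| + |graveyard| holds for every
run.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from . import dedup as _dedup
from . import filters as _filters
from . import geoloc as _geoloc
from . import geomask as _geomask
from . import labcodes as _labcodes
from . import quality as _quality
from . import records as _records
from .records import RecordTable


@dataclass
class PipelineConfig:
    """Everything a scrub run needs; every field has a working default."""

    registry: object = None                  # LabCodeRegistry; bundled if None
    dedup_policy: _dedup.DedupPolicy = field(default_factory=_dedup.DedupPolicy)
    filter_config: _filters.FilterConfig = field(default_factory=_filters.FilterConfig)
    mask_selector: _geomask.MaskSelector = field(default_factory=_geomask.MaskSelector)
    mask_layer: object = None                # AdminLayer; masking skipped if None
    verify: bool = False                     # opt-in location verification
    verify_layer: object = None              # AdminLayer of listed countries
    thresholds: _geoloc.VerificationThresholds = field(
        default_factory=_geoloc.VerificationThresholds)
    siteid_map: object = None                # SiteIdMap for US/Canada fallback

    def resolve_registry(self):
        if self.registry is None:
            self.registry = _labcodes.LabCodeRegistry.bundled()
        return self.registry


@dataclass
class ScrubReport:
    """Per-stage bookkeeping of one scrub run."""

    n_input: int = 0
    stages: list = field(default_factory=list)
    reason_counts: Counter = field(default_factory=Counter)
    n_output: int = 0
    n_graveyard: int = 0

    def add_stage(self, name, n_in, n_out, removed, **extra):
        self.stages.append({"stage": name, "n_in": n_in, "n_out": n_out,
                            "n_removed": n_in - n_out, **extra})
        for e in removed:
            self.reason_counts[e.reason.name] += 1

    def conservation_holds(self) -> bool:
        return self.n_input == self.n_output + self.n_graveyard

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "n_output": self.n_output,
                "n_graveyard": self.n_graveyard,
                "conservation_holds": self.conservation_holds(),
                "stages": self.stages,
                "reason_counts": dict(self.reason_counts)}


@dataclass
class ScrubResult:
    scrubbed: RecordTable
    graveyard: pd.DataFrame
    report: ScrubReport


def run_scrub(table: RecordTable, cfg: PipelineConfig | None = None) -> ScrubResult:
    """Run the full scrubbing pipeline on a record table.

    Deterministic: identical input and configuration give identical output.
    Any stage error propagates before anything is returned, so callers
    never see (or write) a partial result.
    """
    cfg = cfg or PipelineConfig()
    registry = cfg.resolve_registry()
    report = ScrubReport(n_input=len(table))
    entries = []

    t = _records.sanitize_strings(table)
    report.add_stage("sanitize", len(table), len(t), [])

    n_in = len(t)
    t, removed = _labcodes.purge_unknown_labs(t, registry)
    entries += removed
    report.add_stage("labcodes", n_in, len(t), removed)

    n_in = len(t)
    t, n_conv, n_clear = _geoloc.standardize_coordinates(t)
    report.add_stage("coordinates", n_in, len(t), [],
                     n_converted=n_conv, n_coords_cleared=n_clear)

    if cfg.verify:
        if cfg.verify_layer is None:
            raise ValueError("verify=True requires a verify_layer")
        n_in = len(t)
        df = t.df.copy()
        actions = Counter()
        for idx, rec in zip(df.index, df.to_dict("records")):
            upd, action = _geoloc.verify_location(
                rec, cfg.verify_layer, cfg.thresholds, cfg.siteid_map)
            actions[action] += 1
            if action != "skipped":
                for col in ("Long", "Lat", "LocAccuracy", "Province"):
                    df.at[idx, col] = upd.get(col, "")
        t = RecordTable(df, provenance=list(t.provenance))
        report.add_stage("verify", n_in, len(t), [], actions=dict(actions))

    n_in = len(t)
    t, removed = _dedup.dedup_table(t, cfg.dedup_policy)
    entries += removed
    report.add_stage("dedup", n_in, len(t), removed)

    n_in = len(t)
    t, removed = _filters.apply_filters(t, cfg.filter_config)
    entries += removed
    report.add_stage("filters", n_in, len(t), removed)

    if cfg.mask_layer is not None:
        n_in = len(t)
        t, n_masked = _geomask.obfuscate(t, cfg.mask_layer, cfg.mask_selector)
        report.add_stage("geomask", n_in, len(t), [], n_masked=n_masked)

    report.n_output = len(t)
    report.n_graveyard = len(entries)
    graveyard = _records.graveyard_frame(entries)
    return ScrubResult(t, graveyard, report)


def summarize(raw: RecordTable, scrubbed: RecordTable) -> pd.DataFrame:
    """Continental summary of a raw/scrubbed pair (delegates to quality)."""
    return _quality.continent_summary(raw, scrubbed)
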