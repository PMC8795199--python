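"""Duplicate grouping, δ13C ranking, and the resolution cascade."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from c14scrub import DedupPolicy, d13c_rank, dedup_table, group_by_labid, resolve_group
from conftest import make_table, record

D13C_BY_RANK = {1: "-25.1", 2: "-35", 3: "0", 4: ""}


def member(idx, age=1000, error=30, la=2, d13c_rank_=4, lon=10.0, lat=45.0,
           source="SrcA"):
    """A full record dict plus the simplified tuple the oracle consumes."""
    rec = record(LabID="OxA-1", Age=str(age), Error=str(error),
                 LocAccuracy=str(la), d13C=D13C_BY_RANK[d13c_rank_],
                 Long="" if lon is None else str(lon),
                 Lat="" if lat is None else str(lat),
                 Source=source, Continent="Europe")
    rec["_idx"] = idx
    simple = {"idx": idx, "age": float(age), "error": float(error), "la": la,
              "d13c_rank": d13c_rank_, "lon": lon, "lat": lat, "source": source}
    return rec, simple


@pytest.mark.parametrize("value,rank", [
    ("-25.1", 1), ("-30", 1), ("-1", 1),    # band is inclusive
    ("-35", 2), ("5.2", 2), ("-30.01", 2),
    ("0", 3), ("0.0", 3),
    ("", 4), ("n/a", 4),
])
def test_d13c_rank(value, rank):
    assert d13c_rank(value) == rank


class TestGrouping:
    def test_pairs_and_singletons(self):
        t = make_table([{"LabID": x} for x in
                        ["OxA-1", "OxA-2", "OxA-1", "Beta-9", "Beta-9", "Q-1"]])
        groups = group_by_labid(t)
        sizes = sorted(len(g) for g in groups.values())
        assert sizes == [1, 1, 2, 2]

    def test_case_and_whitespace_variants_group_together(self):
        t = make_table([{"LabID": "OxA-1"}, {"LabID": "OXA-1"},
                        {"LabID": "oxa - 1"}])
        assert len(group_by_labid(t)) == 1

    def test_empty_table(self):
        assert group_by_labid(make_table([])) == {}


class TestResolveGroup:
    def test_age_mismatch_deletes_all(self):
        a, _ = member(0, age=1000)
        b, _ = member(1, age=1200)
        kept, removed = resolve_group([a, b])
        assert kept is None
        assert {e.reason.name for e in removed} == {"AGE_MISMATCH"}
        assert len(removed) == 2

    def test_error_mismatch_also_deletes_all(self):
        a, _ = member(0, error=30)
        b, _ = member(1, error=60)
        kept, removed = resolve_group([a, b])
        assert kept is None and len(removed) == 2

    def test_true_duplicates_merge_sources(self):
        a, _ = member(0, source="A")
        b, _ = member(1, source="B")
        kept, removed = resolve_group([a, b])
        assert kept["Source"] == "A; B"
        assert [e.reason.name for e in removed] == ["TRUE_DUPLICATE"]

    def test_priority_source_wins(self):
        a, _ = member(0, source="CARD", lon=10.0)
        b, _ = member(1, source="UWyo2021", lon=10.2)
        kept, removed = resolve_group([a, b])
        assert kept["Source"] == "UWyo2021"

    def test_highest_loc_accuracy_wins(self):
        a, _ = member(0, la=1, lon=10.0)
        b, _ = member(1, la=3, lon=10.2)
        kept, _ = resolve_group([a, b])
        assert kept["LocAccuracy"] == "3"

    def test_location_conflict_beyond_fuzz_deletes_all(self):
        a, _ = member(0, lon=10.0)
        b, _ = member(1, lon=11.0)
        kept, removed = resolve_group([a, b])
        assert kept is None
        assert {e.reason.name for e in removed} == {"LOCATION_CONFLICT"}

    def test_within_fuzz_keeps_winner_coordinates_unchanged(self):
        a, _ = member(0, lon=10.0, source="A")
        b, _ = member(1, lon=10.3, source="B")
        kept, _ = resolve_group([a, b])
        assert kept["Source"] == "A"          # lexicographic tie-break
        assert float(kept["Long"]) == 10.0    # no averaging


class TestCascadeAgainstOracle:
    """Exhaustive pair enumeration against the independent rule oracle."""

    CONFIGS = list(itertools.product(
        [True, False],                       # ages match?
        range(4), range(4),                  # LocAccuracy a, b
        range(1, 5), range(1, 5),            # d13c rank a, b
        [0.0, 0.4, 0.6],                     # lon offset of b
        [("UWyo2021", "CARD"), ("CARD", "UWyo2021"),
         ("SrcA", "SrcB"), ("SrcB", "SrcB")],
    ))

    def test_exhaustive_pairs(self):
        from oracles import oracle_resolve
        mismatches = []
        for (age_match, la_a, la_b, r_a, r_b, off, (src_a, src_b)) in self.CONFIGS:
            lon_a, lat_a = (10.0, 45.0) if la_a > 0 else (None, None)
            lon_b, lat_b = (10.0 + off, 45.0) if la_b > 0 else (None, None)
            a, sa = member(0, age=1000, la=la_a, d13c_rank_=r_a,
                           lon=lon_a, lat=lat_a, source=src_a)
            b, sb = member(1, age=1000 if age_match else 1200, la=la_b,
                           d13c_rank_=r_b, lon=lon_b, lat=lat_b, source=src_b)
            kept, removed = resolve_group([a, b])
            want_idx, want_reasons = oracle_resolve([sa, sb])
            got_idx = kept["_idx"] if kept is not None else None
            got_reasons = {e.record["_idx"]: e.reason.name for e in removed}
            if (got_idx, got_reasons) != (want_idx, want_reasons):
                mismatches.append((age_match, la_a, la_b, r_a, r_b, off,
                                   src_a, src_b, got_idx, want_idx,
                                   got_reasons, want_reasons))
        assert not mismatches, mismatches[:5]

    def test_triples_against_oracle(self):
        from oracles import oracle_resolve
        cases = itertools.product(range(4), range(1, 5), [0.0, 0.4, 0.6],
                                  ["SrcA", "SrcB", "UWyo2021"])
        for la_c, r_c, off_c, src_c in cases:
            a, sa = member(0, la=2, d13c_rank_=2, lon=10.0, source="SrcA")
            b, sb = member(1, la=2, d13c_rank_=2, lon=10.4, source="SrcB")
            lon_c = (10.0 + off_c) if la_c > 0 else None
            c, sc = member(2, la=la_c, d13c_rank_=r_c, lon=lon_c,
                           lat=45.0 if la_c > 0 else None, source=src_c)
            kept, removed = resolve_group([a, b, c])
            want_idx, want_reasons = oracle_resolve([sa, sb, sc])
            got_idx = kept["_idx"] if kept is not None else None
            got_reasons = {e.record["_idx"]: e.reason.name for e in removed}
            assert (got_idx, got_reasons) == (want_idx, want_reasons), \
                (la_c, r_c, off_c, src_c)


class TestTableLevel:
    def _table(self):
        return make_table([
            record(LabID="OxA-1", Age="1000", Error="30", LocAccuracy="2",
                   Long="10.0", Lat="45.0", Source="A", Continent="Europe"),
            record(LabID="OXA-1", Age="1000", Error="30", LocAccuracy="2",
                   Long="10.0", Lat="45.0", Source="B", Continent="Europe"),
            record(LabID="Beta-2", Age="500", Error="40", LocAccuracy="1",
                   Source="A", Continent="Europe"),
        ])

    def test_partition_and_unique_ids(self):
        kept, removed = dedup_table(self._table())
        assert len(kept) + len(removed) == 3
        ids = [x.casefold() for x in kept.df["LabID"]]
        assert len(ids) == len(set(ids))

    def test_idempotent(self):
        kept, _ = dedup_table(self._table())
        again, removed = dedup_table(kept)
        assert removed == []
        assert list(again.df["LabID"]) == list(kept.df["LabID"])

    @given(st.permutations(range(4)))
    @settings(max_examples=24, deadline=None)
    def test_permutation_invariance(self, order):
        rows = [
            record(LabID="OxA-1", Age="1000", Error="30", LocAccuracy="2",
                   Long="10.0", Lat="45.0", Source="B", Continent="Europe"),
            record(LabID="OxA-1", Age="1000", Error="30", LocAccuracy="2",
                   Long="10.2", Lat="45.0", Source="A", Continent="Europe"),
            record(LabID="Wk-9", Age="2000", Error="50", LocAccuracy="3",
                   Long="1.0", Lat="2.0", Source="C", Continent="Asia"),
            record(LabID="OxA-1", Age="1000", Error="30", LocAccuracy="1",
                   Long="10.1", Lat="45.0", Source="C", Continent="Europe"),
        ]
        base_kept, base_removed = dedup_table(make_table(rows))
        perm_kept, perm_removed = dedup_table(make_table([rows[i] for i in order]))
        def canon(df):
            return sorted(map(tuple, df.df.values.tolist()))
        assert canon(base_kept) == canon(perm_kept)
        assert sorted(e.reason.name for e in base_removed) == \
            sorted(e.reason.name for e in perm_removed)


def test_policy_validation():
    with pytest.raises(ValueError):
        DedupPolicy(fuzz_deg=0)
    with pytest.raises(ValueError):
        DedupPolicy(d13c_band=(0, -1))
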