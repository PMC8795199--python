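"""Summary identities, KDE/risk surfaces, densities, and SMA fits."""

import numpy as np
import pytest

from c14scrub import (GridSpec, continent_summary, density_per_unit, kde2d,
                      risk_surface, site_index, sma_fit, summary_from_counts)
from c14scrub.synth import (generate_admin_grid, generate_clustered_sites,
                            generate_loglog_units)
from conftest import make_table, record


class TestSiteIndex:
    def test_shared_key_is_one_site(self):
        t = make_table([record(SiteName="A", SiteID="", Lat="1", Long="2")] * 3)
        idx = site_index(t)
        assert len(idx) == 1 and idx.loc[0, "n_dates"] == 3

    def test_same_name_different_coordinates_is_two_sites(self):
        t = make_table([record(SiteName="A", Lat="1", Long="2"),
                        record(SiteName="A", Lat="1", Long="3")])
        assert len(site_index(t)) == 2

    def test_counts_sum_to_table_size(self):
        t = make_table([record(SiteName=f"S{i % 4}", Lat="0", Long="0")
                        for i in range(10)])
        assert site_index(t)["n_dates"].sum() == 10

    def test_empty_table(self):
        assert len(site_index(make_table([]))) == 0


class TestSummary:
    PRINTED = {
        "Africa": (14860, 11129, 3463),
        "Asia": (21828, 14071, 2693),
        "Australia": (3661, 3657, 1530),
        "Europe": (119106, 77393, 21331),
        "North America": (102288, 64934, 16120),
        "Central America": (1223, 1218, 991),
        "South America": (9568, 7668, 2077),
    }

    def test_printed_count_identities(self):
        df = summary_from_counts(self.PRINTED, total_dated_sites=47313)
        by = df.set_index("Continent")
        assert by.loc["Africa", "PctKept"] == 74.9
        assert by.loc["Africa", "MeanDatesPerSite"] == 3.21
        assert by.loc["Australia", "PctKept"] == 99.9
        assert by.loc["Europe", "MeanDatesPerSite"] == 3.63
        assert by.loc["Total", "PctKept"] == 66.1
        assert by.loc["Total", "MeanDatesPerSite"] == 3.81

    def test_scrubbed_counts_sum(self):
        df = summary_from_counts(self.PRINTED)
        assert df.set_index("Continent").loc["Total", "ScrubbedDates"] == 180_070

    def test_site_total_discrepancy_surfaced_not_hidden(self):
        df = summary_from_counts(self.PRINTED, total_dated_sites=47313)
        total = df.set_index("Continent").loc["Total"]
        assert total["DatedSites"] == 47313
        assert total["DatedSitesRowSum"] == 48205

    def test_zero_scrubbed_continent(self):
        df = summary_from_counts({"Atlantis": (10, 0, 0)})
        row = df.set_index("Continent").loc["Atlantis"]
        assert row["PctKept"] == 0.0 and row["MeanDatesPerSite"] is None

    def test_from_tables_recomputes_identities(self):
        raw = make_table(
            [record(LabID=f"A-{i}", Continent="Borealia") for i in range(8)]
            + [record(LabID=f"B-{i}", Continent="Australis") for i in range(4)])
        scr = make_table(
            [record(LabID=f"A-{i}", Continent="Borealia", SiteName=f"S{i % 2}",
                    Lat="1", Long="2") for i in range(6)]
            + [record(LabID="B-0", Continent="Australis", SiteName="T",
                      Lat="3", Long="4")])
        df = continent_summary(raw, scr).set_index("Continent")
        assert df.loc["Borealia", "PctKept"] == 75.0
        assert df.loc["Borealia", "DatedSites"] == 2
        assert df.loc["Borealia", "MeanDatesPerSite"] == 3.0
        assert df.loc["Total", "ScrubbedDates"] == 7

    def test_empty_raw_rejected(self):
        with pytest.raises(ValueError, match="no records"):
            continent_summary(make_table([]), make_table([]))


class TestKde2d:
    def test_single_point_integrates_to_one(self):
        s = kde2d(np.array([[0.0, 0.0]]), bandwidth=(0.5, 0.5),
                  grid=GridSpec(201, 201, (-5, 5, -5, 5)))
        assert s.integral() == pytest.approx(1.0, abs=1e-6)

    def test_mirror_symmetric_points_give_symmetric_surface(self):
        pts = np.array([[-1.0, 0.0], [1.0, 0.0]])
        s = kde2d(pts, bandwidth=(0.4, 0.4), grid=GridSpec(41, 21, (-3, 3, -1, 1)))
        assert np.allclose(s.z, s.z[:, ::-1], atol=1e-12)

    def test_matches_brute_force_summation(self):
        from oracles import oracle_kde
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 5, (20, 2))
        w = rng.uniform(0.5, 4.0, 20)
        grid = GridSpec(15, 15, (-1, 6, -1, 6))
        s = kde2d(pts, weights=w, bandwidth=(0.7, 0.9), grid=grid)
        gx, gy = grid.axes()
        assert np.max(np.abs(s.z - oracle_kde(pts, w, 0.7, 0.9, gx, gy))) < 1e-10

    def test_parameter_errors(self):
        with pytest.raises(ValueError):
            kde2d(np.empty((0, 2)))
        with pytest.raises(ValueError):
            kde2d(np.array([[0.0, 0.0]]), bandwidth=(0.0, 1.0))


class TestRiskSurface:
    def _surfaces(self, weights):
        pts, w = generate_clustered_sites(2, 40, weights, seed=3)
        grid = GridSpec(40, 20, (-2, 7, -2, 2))
        bw = (0.6, 0.6)
        return (kde2d(pts, weights=w, bandwidth=bw, grid=grid),
                kde2d(pts, bandwidth=bw, grid=grid))

    def test_equal_weights_give_unit_ratio(self):
        weighted, unweighted = self._surfaces([2.0, 2.0])
        surf = risk_surface(weighted, unweighted)
        defined = ~np.isnan(surf.ratio)
        assert defined.any()
        assert np.allclose(surf.ratio[defined], 1.0, atol=1e-9)

    def test_heavy_cluster_ratio_above_one(self):
        weighted, unweighted = self._surfaces([1.0, 10.0])
        surf = risk_surface(weighted, unweighted)
        gx = weighted.x
        heavy = surf.ratio[:, gx > 3.5]
        light = surf.ratio[:, gx < 1.5]
        assert np.nanmean(heavy) > 1.0 > np.nanmean(light)

    def test_low_density_cells_masked(self):
        weighted, unweighted = self._surfaces([1.0, 1.0])
        surf = risk_surface(weighted, unweighted, epsilon=1e9)
        assert np.isnan(surf.ratio).all()

    def test_grid_mismatch_rejected(self):
        a = kde2d(np.array([[0.0, 0.0]]), bandwidth=(1, 1),
                  grid=GridSpec(10, 10, (-3, 3, -3, 3)))
        b = kde2d(np.array([[0.0, 0.0]]), bandwidth=(1, 1),
                  grid=GridSpec(11, 10, (-3, 3, -3, 3)))
        with pytest.raises(ValueError):
            risk_surface(a, b)


class TestDensityPerUnit:
    def test_counts_over_area(self):
        layer = generate_admin_grid(2, 1, 2.0)  # two 2x2-degree cells
        t = make_table(
            [record(LabID=f"A-{i}", SiteName=f"S{i}", Long="0.5", Lat="0.5")
             for i in range(10)]
            + [record(LabID="B-0", SiteName="S0", Long="0.5", Lat="0.5")])
        df = density_per_unit(t, layer).set_index("unit")
        left = df.loc["cell-00-00"]
        assert left["n_sites"] == 10            # S0..S9 distinct keys
        assert left["site_density"] == pytest.approx(10 / 4.0)
        assert left["n_dates"] == 11
        assert not df.loc["cell-01-00", "included"]

    def test_zero_site_units_flagged_for_exclusion(self):
        layer = generate_admin_grid(3, 1, 1.0)
        t = make_table([record(LabID="A-1", SiteName="S", Long="0.5", Lat="0.5")])
        df = density_per_unit(t, layer)
        assert df["included"].sum() == 1


class TestSmaFit:
    def test_exact_line(self):
        fit = sma_fit([1, 2, 3], [2, 4, 6])
        assert (fit.slope, fit.intercept, fit.r) == (2.0, 0.0, 1.0)

    def test_negative_relationship_gets_negative_slope(self):
        assert sma_fit([1, 2, 3], [6, 4, 2]).slope == -2.0

    def test_slope_magnitude_is_sd_ratio_and_line_through_centroid(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1.3, 200)
        y = 0.7 + 1.9 * x + rng.normal(0, 0.4, 200)
        fit = sma_fit(x, y)
        r = np.corrcoef(x, y)[0, 1]
        assert abs(fit.slope) == pytest.approx(np.std(y, ddof=1) / np.std(x, ddof=1))
        assert np.sign(fit.slope) == np.sign(r)
        assert np.mean(y) == pytest.approx(fit.intercept + fit.slope * np.mean(x))

    def test_swap_symmetry_slope_reciprocal(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 50)
        y = 2 + 0.8 * x + rng.normal(0, 0.2, 50)
        assert sma_fit(x, y).slope == pytest.approx(1 / sma_fit(y, x).slope)

    def test_recovers_generative_loglog_slope(self):
        for b in (0.8, 1.0, 1.3):
            slopes = []
            for rep in range(100):
                units = generate_loglog_units(50, b, seed=1000 * rep + int(b * 10))
                fit = sma_fit(np.log10(units["site_density"]),
                              np.log10(units["date_density"]))
                slopes.append(fit.slope)
            assert np.mean(slopes) == pytest.approx(b, abs=0.1)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            sma_fit([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError):
            sma_fit([1, 2], [1, 2])
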