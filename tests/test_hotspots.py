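"""Natural-breaks classification, area arithmetic and composition reports."""

import itertools

import numpy as np
import pandas as pd
import pytest

import avistack as av
from avistack.grids import GridSpec, PAMask
from avistack.stacking import RichnessMap

# The published hotspot intervals for a 182-species maximum richness surface.
PRINTED_INTERVALS = [(1, 99), (100, 149), (150, 182)]


def brute_force_jenks_ss(values, n_classes):
    """Minimum total within-class sum of squares over all ordered partitions."""
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)

    def ss(seg):
        return float(np.sum((seg - seg.mean()) ** 2))

    best = np.inf
    for cuts in itertools.combinations(range(1, n), n_classes - 1):
        edges = [0, *cuts, n]
        # identical values must not straddle a break for a valid classification
        if any(v[e - 1] == v[e] for e in cuts):
            continue
        total = sum(ss(v[a:b]) for a, b in zip(edges, edges[1:]))
        best = min(best, total)
    return best


def classes_ss(values, classes):
    v = np.asarray(values, dtype=float)
    total = 0.0
    for lo, hi in classes.bounds:
        seg = v[(v >= lo) & (v <= hi)]
        total += float(np.sum((seg - seg.mean()) ** 2))
    return total


class TestJenksBreaks:
    def test_worked_example(self):
        cl = av.jenks_breaks([1, 2, 3, 10, 11, 20], 3)
        assert cl.bounds == [(1.0, 3.0), (10.0, 11.0), (20.0, 20.0)]

    def test_insufficient_distinct_values(self):
        with pytest.raises(ValueError, match="distinct"):
            av.jenks_breaks([4, 4, 4, 4], 2)

    def test_zero_cells_excluded(self):
        cl = av.jenks_breaks([0, 0, 0, 1, 2, 3, 10, 11, 20], 3)
        assert cl.bounds[0][0] == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_dp_matches_brute_force_minimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 26))
        values = rng.integers(1, 60, n).astype(float)
        if np.unique(values).size < 3:
            values = np.arange(1, n + 1, dtype=float)
        cl = av.jenks_breaks(values, 3)
        assert classes_ss(values, cl) == pytest.approx(brute_force_jenks_ss(values, 3), abs=1e-9)


class TestClassifyRichness:
    @pytest.fixture()
    def printed_classes(self):
        return av.HotspotClasses(bounds=[tuple(map(float, b)) for b in PRINTED_INTERVALS])

    @pytest.mark.parametrize("value,expect", [(100, 1), (150, 2), (1, 0), (99, 0), (182, 2)])
    def test_printed_interval_membership(self, printed_classes, value, expect):
        rm = RichnessMap(values=np.array([[float(value)]]))
        assert av.classify_richness(rm, printed_classes)[0, 0] == expect

    def test_zero_and_nodata_unclassified(self, printed_classes):
        rm = RichnessMap(values=np.array([[0.0, np.nan]]))
        out = av.classify_richness(rm, printed_classes)
        assert (out == -1).all()

    def test_every_positive_value_in_exactly_one_class(self):
        values = np.arange(1.0, 183.0)
        rm = RichnessMap(values=values.reshape(1, -1))
        cl = av.HotspotClasses(bounds=[tuple(map(float, b)) for b in PRINTED_INTERVALS])
        out = av.classify_richness(rm, cl)
        assert (out >= 0).all()

    def test_above_top_interval_clips_by_default(self):
        cl = av.HotspotClasses(bounds=[(1.0, 2.0), (3.0, 4.0), (5.0, 6.0)])
        rm = RichnessMap(values=np.array([[9.0]]))
        assert av.classify_richness(rm, cl)[0, 0] == 2
        assert av.classify_richness(rm, cl, clip_above=False)[0, 0] == -1


class TestCellArea:
    def test_planar_cells(self):
        grid = GridSpec(n_rows=2, n_cols=2, planar=True, cell_size_km=1.0)
        np.testing.assert_allclose(av.cell_area_km2(grid), 1.0)

    def test_equator_one_degree(self):
        grid = GridSpec(n_rows=1, n_cols=1, y_origin=0.5, cell_size=1.0)
        assert av.cell_area_km2(grid)[0, 0] == pytest.approx(111.32**2)

    def test_cosine_latitude_scaling(self):
        grid = GridSpec(n_rows=1, n_cols=1, cell_size=0.01)
        a0 = av.cell_area_km2(grid, latitude=0.0)[0, 0]
        a60 = av.cell_area_km2(grid, latitude=60.0)[0, 0]
        assert a60 / a0 == pytest.approx(0.5, abs=1e-9)


class TestGapAnalysis:
    def test_worked_example_hotspots(self):
        rep = av.gap_analysis_table({"hotspot": (1420.28, 732.09)})
        row = rep.row("hotspot")
        assert row["protected_pct"] == 51.55
        assert row["gap_km2"] == 688.19

    def test_worked_example_subhotspots(self):
        rep = av.gap_analysis_table({"sub-hotspot": (3367.11, 845.69)})
        row = rep.row("sub-hotspot")
        assert row["protected_pct"] == 25.12
        assert row["gap_km2"] == 2521.42

    def test_full_protection(self):
        cl = av.HotspotClasses(bounds=[(1.0, 5.0), (6.0, 8.0), (9.0, 10.0)])
        raster = np.array([[0, 1, 2], [2, 1, 0]])
        grid = GridSpec(n_rows=2, n_cols=3, planar=True, cell_size_km=1.0)
        pa = PAMask(grid=grid, mask=np.ones((2, 3), dtype=bool))
        rep = av.gap_analysis(raster, cl, pa, av.cell_area_km2(grid))
        assert (rep.table["gap_km2"] == 0).all()
        assert (rep.table.loc[rep.table["total_km2"] > 0, "protected_pct"] == 100.0).all()

    def test_conservation_protected_plus_gap_equals_total(self):
        rng = np.random.default_rng(3)
        raster = rng.integers(-1, 3, (20, 20))
        grid = GridSpec(n_rows=20, n_cols=20)
        pa = PAMask(grid=grid, mask=rng.uniform(size=(20, 20)) < 0.4)
        cl = av.HotspotClasses(bounds=[(1.0, 3.0), (4.0, 6.0), (7.0, 9.0)])
        rep = av.gap_analysis(raster, cl, pa, av.cell_area_km2(grid))
        t = rep.table
        np.testing.assert_allclose(t["protected_km2"] + t["gap_km2"], t["total_km2"], atol=0.02)

    def test_misaligned_grids_rejected(self):
        cl = av.HotspotClasses(bounds=[(1.0, 2.0), (3.0, 4.0), (5.0, 6.0)])
        grid = GridSpec(n_rows=2, n_cols=2)
        pa = PAMask(grid=grid, mask=np.zeros((2, 2), dtype=bool))
        with pytest.raises(ValueError, match="grid"):
            av.gap_analysis(np.zeros((3, 3)), cl, pa, np.ones((2, 2)))

    def test_protected_exceeding_total_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            av.gap_analysis_table({"hotspot": (10.0, 11.0)})


class TestCompositionSummary:
    @pytest.fixture()
    def community_counts(self):
        rows = (
            [{"species": f"p{i}", "order": "Passeriformes", "residency": "resident"} for i in range(133)]
            + [{"species": f"c{i}", "order": "Charadriiformes", "residency": "migratory"} for i in range(62)]
            + [{"species": f"o{i}", "order": "other", "residency": "migratory"} for i in range(117)]
        )
        df = pd.DataFrame(rows)
        df["residency"] = ["resident"] * 82 + ["migratory"] * 230
        return df

    def test_printed_percentages(self, community_counts):
        rep = av.composition_summary(community_counts, denominator=312)
        rep = rep.set_index(["group", "level"])
        assert rep.loc[("order", "Passeriformes"), "percent"] == 42.63
        assert rep.loc[("order", "Charadriiformes"), "percent"] == 19.87
        assert rep.loc[("residency", "resident"), "percent"] == 26.28
        assert rep.loc[("residency", "migratory"), "percent"] == 73.72

    def test_share_of_larger_pool(self):
        df = pd.DataFrame({"species": [f"s{i}" for i in range(468)], "present": ["yes"] * 468})
        rep = av.composition_summary(df, denominator=1580)
        assert rep.iloc[0]["percent"] == 29.62

    def test_partition_percentages_sum_to_hundred(self, community_counts):
        rep = av.composition_summary(community_counts, denominator=312)
        for _, grp in rep.groupby("group"):
            assert grp["percent"].sum() == pytest.approx(100.0, abs=0.02)

    def test_empty_traits(self):
        assert av.composition_summary(pd.DataFrame(), denominator=10).empty
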