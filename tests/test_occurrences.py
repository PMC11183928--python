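"""Record cleaning, the minimum-sample rule, grid dedup and spatial thinning."""

import itertools

import numpy as np
import pandas as pd
import pytest

import avistack as av
from avistack.grids import haversine_km

EXTENT = (0.0, 40.0, 20.0, 60.0)


def _table(species, lons, lats, dates=None):
    n = len(lons)
    return pd.DataFrame(
        {
            "species": species if isinstance(species, list) else [species] * n,
            "longitude": lons,
            "latitude": lats,
            "date": dates or ["2018-06-01"] * n,
            "residency": "resident",
            "diet": "carnivorous",
            "china_class": "none",
            "iucn": "LC",
        }
    )


class TestCleanRecords:
    def test_empty_input(self):
        out = av.clean_records(_table("a", [], []), EXTENT)
        assert out.empty

    def test_each_rule_applied(self, occurrence_table):
        out = av.clean_records(occurrence_table, EXTENT)
        # duplicate removed, missing coordinate removed, out-of-window removed,
        # out-of-extent removed -> 3 distinct valid rows survive
        assert len(out) == 3
        assert out["species"].tolist() == ["a", "a", "b"]

    def test_window_boundary_is_inclusive(self):
        t = _table("a", [10, 10.1, 10.2], [50, 50, 50],
                   ["2012-12-31", "2013-01-01", "2023-12-31"])
        out = av.clean_records(t, EXTENT, date_window=("2013-01-01", "2023-12-31"))
        assert out["date"].tolist() == ["2013-01-01", "2023-12-31"]

    def test_preserves_input_order_and_columns(self, occurrence_table):
        out = av.clean_records(occurrence_table, EXTENT)
        assert list(out.columns) == list(occurrence_table.columns)
        assert list(out.index) == sorted(out.index)

    def test_idempotent(self, occurrence_table):
        once = av.clean_records(occurrence_table, EXTENT)
        twice = av.clean_records(once, EXTENT)
        pd.testing.assert_frame_equal(once, twice)


class TestFilterMinRecords:
    def test_boundary_at_threshold(self):
        t = pd.concat([_table("a", [10] * 14, [50] * 14), _table("b", [10] * 15, [50] * 15)])
        out = av.filter_min_records(t, 15)
        assert set(out["species"]) == {"b"}

    def test_counts_after_rule(self):
        t = pd.concat(
            [_table("a", [10] * 14, [50] * 14),
             _table("b", [10] * 15, [50] * 15),
             _table("c", [10] * 40, [50] * 40)]
        )
        out = av.filter_min_records(t, 15)
        assert out["species"].nunique() == 2
        assert len(out) == 55


class TestGridDedup:
    def test_same_cell_keeps_one(self):
        t = _table("a", [10.001, 10.002], [50.001, 50.002])
        assert len(av.grid_dedup(t, 2.5, seed=0)) == 1

    def test_distinct_cells_unchanged(self):
        t = _table("a", [10.0, 11.0, 12.0], [50.0, 50.0, 50.0])
        out = av.grid_dedup(t, 2.5, seed=0)
        assert len(out) == 3

    def test_three_cells_keep_three(self):
        # 7 records spread over 3 distinct 2.5-arcmin cells
        lons = [10.00, 10.01, 10.01, 10.10, 10.10, 10.20, 10.20]
        t = _table("a", lons, [50.0] * 7)
        out = av.grid_dedup(t, 2.5, seed=1, anchor=(10.0, 50.1))
        assert len(out) == 3

    def test_species_deduped_independently(self):
        t = pd.concat([_table("a", [10.0], [50.0]), _table("b", [10.0], [50.0])])
        assert len(av.grid_dedup(t, 2.5, seed=0)) == 2

    def test_idempotent(self):
        t = _table("a", np.linspace(10, 10.3, 9).tolist(), [50.0] * 9)
        once = av.grid_dedup(t, 2.5, seed=3, anchor=(10.0, 50.1))
        twice = av.grid_dedup(once, 2.5, seed=3, anchor=(10.0, 50.1))
        pd.testing.assert_frame_equal(once, twice)


def brute_force_max_thinned(lons, lats, d_km):
    """Exhaustive maximum subset with all pairwise distances >= d_km."""
    n = len(lons)
    best = 0
    for r in range(n, 0, -1):
        for combo in itertools.combinations(range(n), r):
            ok = all(
                haversine_km(lons[i], lats[i], lons[j], lats[j]) >= d_km
                for i, j in itertools.combinations(combo, 2)
            )
            if ok:
                return r
    return best


class TestThinSpatial:
    def test_single_record_unchanged(self):
        t = _table("a", [10.0], [50.0])
        pd.testing.assert_frame_equal(av.thin_spatial(t, 5.0, seed=0), t)

    def test_collinear_endpoints_survive(self):
        # points at ~0, 1, 2 km along a meridian; thin at 1.5 km
        km_per_deg = 111.19493
        lats = [50.0, 50.0 + 1 / km_per_deg, 50.0 + 2 / km_per_deg]
        t = _table("a", [10.0] * 3, lats)
        out = av.thin_spatial(t, 1.5, seed=0)
        assert len(out) == 2
        assert set(out["latitude"]) == {lats[0], lats[2]}

    def test_min_distance_invariant(self):
        rng = np.random.default_rng(5)
        t = _table("a", (10 + rng.uniform(0, 0.05, 30)).tolist(),
                   (50 + rng.uniform(0, 0.05, 30)).tolist())
        out = av.thin_spatial(t, 2.0, seed=1)
        lon = out["longitude"].to_numpy()
        lat = out["latitude"].to_numpy()
        dm = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
        np.fill_diagonal(dm, np.inf)
        assert dm.min() >= 2.0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_maximum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        lons = 10 + rng.uniform(0, 0.06, n)
        lats = 50 + rng.uniform(0, 0.06, n)
        t = _table("a", lons.tolist(), lats.tolist())
        out = av.thin_spatial(t, 2.5, seed=seed)
        assert len(out) == brute_force_max_thinned(lons, lats, 2.5)

    def test_idempotent(self):
        rng = np.random.default_rng(9)
        t = _table("a", (10 + rng.uniform(0, 0.04, 15)).tolist(),
                   (50 + rng.uniform(0, 0.04, 15)).tolist())
        once = av.thin_spatial(t, 1.0, seed=2)
        twice = av.thin_spatial(once, 1.0, seed=2)
        pd.testing.assert_frame_equal(once, twice)


class TestPrepareOccurrences:
    def test_funnel_logs_counts_and_flags(self):
        rng = np.random.default_rng(2)
        t = pd.concat(
            [_table("a", (10 + rng.uniform(0, 1, 40)).tolist(), (50 + rng.uniform(0, 1, 40)).tolist()),
             _table("b", (10 + rng.uniform(0, 0.01, 20)).tolist(), (50 + rng.uniform(0, 0.01, 20)).tolist())],
        ).reset_index(drop=True)
        out, log = av.prepare_occurrences(t, EXTENT, min_records=15, dedup_arcmin=2.5,
                                          thin_km=1.0, seed=0)
        stages = [s["stage"] for s in log.stages]
        assert stages == ["input", "clean", "grid_dedup", "min_records", "thin"]
        assert log.stages[0]["n_records"] == 60
        # species b collapses onto very few cells and is dropped by the
        # minimum-sample rule before thinning
        assert set(out["species"]) <= {"a"}
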