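import numpy as np
import pytest

from palmcell import synthetic as syn
from palmcell.clustering import (
    FWHM_FACTOR,
    ClusterParams,
    classify_cluster,
    cluster_fwhm,
    cluster_motion,
    event_time_stats,
    filter_components,
    find_clusters,
    grow_merge_clusters,
    label_components,
    rasterize_localizations,
)
from palmcell.io_core import LocalizationTable


def _table(x, y, frames=None, **kw):
    n = len(x)
    return LocalizationTable.from_arrays(
        frame=np.zeros(n, dtype=int) if frames is None else frames,
        x_nm=x, y_nm=y, **kw,
    )


def union_find_components(grid):
    """Independent oracle: count 8-connected components by union-find."""
    h, w = grid.shape
    parent = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    cells = [(r, c) for r in range(h) for c in range(w) if grid[r, c]]
    for cell in cells:
        parent[cell] = cell
    for (r, c) in cells:
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                n = (r + dr, c + dc)
                if n != (r, c) and n in parent:
                    union((r, c), n)
    return len({find(c) for c in cells})


class TestRasterize:
    def test_empty_table_gives_empty_grid(self):
        grid, index, _ = rasterize_localizations(LocalizationTable.empty(), ClusterParams())
        assert grid.size == 0 and index == {}

    def test_single_event_sets_exactly_one_pixel(self):
        grid, index, _ = rasterize_localizations(_table([55.0], [23.0]), ClusterParams())
        assert grid.sum() == 1 and len(index) == 1

    def test_floor_convention_separates_3nm_and_12nm(self):
        t = _table([3.0, 12.0], [0.0, 0.0])
        grid, index, origin = rasterize_localizations(
            t, ClusterParams(virtual_pixel_nm=10.0), roi=(0, 0, 100, 100)
        )
        assert grid.sum() == 2
        assert {(0, 0), (0, 1)} == set(index)

    def test_index_maps_pixels_to_their_events(self):
        t = _table([1.0, 2.0, 55.0], [1.0, 2.0, 1.0])
        _, index, _ = rasterize_localizations(
            t, ClusterParams(virtual_pixel_nm=10.0), roi=(0, 0, 100, 100)
        )
        assert sorted(index[(0, 0)]) == [0, 1]
        assert index[(0, 5)] == [2]


class TestLabeling:
    def test_single_pixel_is_one_component(self):
        grid = np.zeros((5, 5), dtype=bool)
        grid[2, 2] = True
        _, n = label_components(grid)
        assert n == 1

    def test_diagonal_pixels_join_under_8_connectivity(self):
        grid = np.zeros((4, 4), dtype=bool)
        grid[0, 0] = grid[1, 1] = True
        _, n = label_components(grid)
        assert n == 1

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_union_find_oracle_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        grid = rng.random((30, 30)) < rng.uniform(0.05, 0.5)
        _, n = label_components(grid)
        assert n == union_find_components(grid)


class TestFiltering:
    def _setup(self, events_per_obj, areas):
        """Build labeled grid + index with given event counts and pixel areas."""
        grid = np.zeros((20, 20), dtype=bool)
        index = {}
        eid = 0
        for i, (n_ev, area) in enumerate(zip(events_per_obj, areas)):
            row = i * 4
            pixels = [(row, c) for c in range(area)]
            for px in pixels:
                grid[px] = True
                index[px] = []
            for k in range(n_ev):
                index[pixels[k % area]].append(eid)
                eid += 1
        labeled, n = label_components(grid)
        return labeled, n, index

    def test_too_few_events_discarded(self):
        labeled, n, index = self._setup([4, 10], [3, 3])
        cands, disc = filter_components(labeled, n, index, ClusterParams(min_events=5))
        assert len(cands) == 1 and len(disc) == 1
        assert "n_events" in disc[0]["reason"]

    def test_single_pixel_area_discarded_regardless_of_events(self):
        labeled, n, index = self._setup([50], [1])
        cands, disc = filter_components(labeled, n, index, ClusterParams(min_events=5))
        assert cands == [] and "area" in disc[0]["reason"]

    def test_objects_above_both_thresholds_all_kept(self):
        labeled, n, index = self._setup([30, 25], [4, 3])
        cands, disc = filter_components(labeled, n, index, ClusterParams(min_events=20))
        assert len(cands) == 2 and disc == []


class TestGrowMerge:
    def test_isolated_cluster_unchanged(self):
        rng = np.random.default_rng(0)
        xy = np.vstack([rng.normal(0, 10, (50, 2)), [[5000.0, 5000.0]]])
        t = _table(xy[:, 0] + 6000, xy[:, 1] + 6000)
        params = ClusterParams(min_events=20, merge_step_nm=50.0)
        cands = [{"label": 1, "pixels": [], "event_ids": list(range(50))}]
        recs = grow_merge_clusters(cands, t, params)
        assert len(recs) == 1 and recs[0].n_events == 50

    def test_two_nearby_candidates_merge_by_five_percent_rule(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 8, (50, 2)) + [1000.0, 1000.0]
        b = rng.normal(0, 8, (50, 2)) + [1040.0, 1000.0]
        xy = np.vstack([a, b])
        t = _table(xy[:, 0], xy[:, 1])
        cands = [
            {"label": 1, "pixels": [], "event_ids": list(range(50))},
            {"label": 2, "pixels": [], "event_ids": list(range(50, 100))},
        ]
        recs = grow_merge_clusters(cands, t, ClusterParams(merge_step_nm=50.0))
        assert len(recs) == 1
        assert recs[0].n_events == 100

    def test_distant_noise_never_absorbed(self, demo_field):
        table, truth = demo_field
        recs = find_clusters(table, ClusterParams())
        labels = truth["label_of_id"]
        for rec in recs:
            member_labels = {labels[i] for i in rec.member_ids}
            assert -1 not in member_labels

    def test_partition_property_every_event_in_at_most_one_cluster(self, demo_field):
        table, _ = demo_field
        recs = find_clusters(table, ClusterParams())
        all_ids = np.concatenate([r.member_ids for r in recs])
        assert len(all_ids) == len(np.unique(all_ids))

    def test_row_order_permutation_invariance(self, demo_field):
        table, _ = demo_field
        recs_a = find_clusters(table, ClusterParams())
        shuffled = table.df.sample(frac=1.0, random_state=0)
        recs_b = find_clusters(table.with_df(shuffled), ClusterParams())
        assert len(recs_a) == len(recs_b)
        for a, b in zip(recs_a, recs_b):
            np.testing.assert_array_equal(a.member_ids, b.member_ids)

    def test_merging_never_increases_cluster_count(self, demo_field):
        table, _ = demo_field
        params = ClusterParams()
        grid, index, _ = rasterize_localizations(table, params)
        labeled, n = label_components(grid)
        cands, _ = filter_components(labeled, n, index, params)
        recs = grow_merge_clusters(cands, table, params)
        assert len(recs) <= len(cands)


class TestFWHM:
    def test_identical_positions_give_zero(self):
        fx, fy, fm, ok = cluster_fwhm(np.zeros((10, 2)))
        assert ok and fm == 0.0

    def test_gaussian_cloud_matches_closed_form(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 25.0, (10_000, 2))
        _, _, fm, _ = cluster_fwhm(pts)
        assert fm == pytest.approx(FWHM_FACTOR * 25.0, abs=1.0)

    def test_anisotropic_cloud_per_axis(self):
        rng = np.random.default_rng(3)
        pts = np.column_stack([rng.normal(0, 15.0, 20_000), rng.normal(0, 60.0, 20_000)])
        fx, fy, _, _ = cluster_fwhm(pts)
        assert fx == pytest.approx(FWHM_FACTOR * 15.0, rel=0.02)
        assert fy == pytest.approx(FWHM_FACTOR * 60.0, rel=0.02)

    def test_single_event_flagged_undefined(self):
        _, _, _, ok = cluster_fwhm(np.array([[1.0, 2.0]]))
        assert not ok


class TestClassification:
    def test_zero_extent_immobile_cluster_is_palm_limited(self):
        t = _table([100.0] * 30, [100.0] * 30, frames=np.arange(30))
        recs = find_clusters(t, ClusterParams(min_events=5))
        # degenerate: all events in one pixel -> area filter removes it; classify directly
        from palmcell.clustering import ClusterRecord

        rec = ClusterRecord(0, np.arange(30), np.array([100.0, 100.0]), 30, 0, 29)
        assert classify_cluster(rec, t) == "palm_limited"

    def test_micron_scale_cluster_is_dynamic(self, demo_field):
        table, truth = demo_field
        recs = find_clusters(table, ClusterParams())
        big = max(recs, key=lambda r: r.fwhm_nm)
        assert big.type == "dynamic"

    def test_precision_sized_immobile_cluster_is_palm_limited(self, demo_field):
        table, _ = demo_field
        recs = find_clusters(table, ClusterParams())
        small = min(recs, key=lambda r: r.fwhm_nm)
        assert small.type == "palm_limited"
        assert small.fwhm_nm <= 1.3 * FWHM_FACTOR * table.loc_precision_nm

    def test_type_recovery_matches_truth_on_clean_scene(self, demo_field):
        table, truth = demo_field
        recs = find_clusters(table, ClusterParams())
        assert len(recs) == truth["n_clusters"]
        labels = truth["label_of_id"]
        kinds = {i: s["kind"] for i, s in enumerate(
            [s for s in truth["specs"] if s["kind"] != "noise"])}
        expect = {"static": "palm_limited", "dynamic": "dynamic"}
        for rec in recs:
            truth_label = labels[rec.member_ids[0]]
            assert rec.type == expect[kinds[truth_label]]


class TestTimeStats:
    def _rec(self, table):
        from palmcell.clustering import ClusterRecord

        ids = table.df["id"].to_numpy()
        return ClusterRecord(0, ids, table.xy.mean(axis=0), len(ids),
                             int(table.frames.min()), int(table.frames.max()))

    def test_events_every_frame_duty_cycle_one(self):
        t = _table(np.zeros(100), np.zeros(100), frames=np.arange(100))
        stats = event_time_stats(self._rec(t), t, n_total_frames=100)
        assert stats["duty_cycle"] == 1.0

    def test_one_event_in_hundred_frames(self):
        t = _table([0.0], [0.0], frames=[40])
        stats = event_time_stats(self._rec(t), t, n_total_frames=100)
        assert stats["duty_cycle"] == pytest.approx(0.01)

    def test_on_and_dark_times_match_generated_schedule(self):
        table, truth = syn.gen_localization_field(
            [{"kind": "static", "center": (0.0, 0.0), "sigma_nm": 10.0, "n_events": 120}],
            seed=4, n_frames=1000,
        )
        frames = np.sort(truth["schedules"][0])
        runs = np.split(frames, np.flatnonzero(np.diff(frames) > 1) + 1)
        expected_on = sorted(len(r) for r in runs)
        expected_dark = sorted(
            runs[i + 1][0] - runs[i][-1] - 1 for i in range(len(runs) - 1)
        )
        stats = event_time_stats(self._rec(table), table, n_total_frames=1000)
        assert sorted(stats["on_times_ms"] / table.frame_time_ms) == expected_on
        assert sorted(stats["dark_times_ms"] / table.frame_time_ms) == expected_dark

    def test_homogeneous_activation_gives_linear_cumulative_curve(self):
        table, _ = syn.gen_localization_field(
            [{"kind": "static", "center": (0.0, 0.0), "sigma_nm": 10.0, "n_events": 300}],
            seed=5, n_frames=2000,
        )
        stats = event_time_stats(self._rec(table), table, n_total_frames=2000)
        assert stats["linearity_r2"] > 0.98


class TestMotion:
    def _rec(self, table):
        from palmcell.clustering import ClusterRecord

        ids = table.df["id"].to_numpy()
        return ClusterRecord(0, ids, table.xy.mean(axis=0), len(ids),
                             int(table.frames.min()), int(table.frames.max()))

    def test_static_cluster_msd_sits_at_noise_floor(self):
        rng = np.random.default_rng(6)
        sigma, window, n = 25.0, 10, 4000
        t = _table(rng.normal(0, sigma, n), rng.normal(0, sigma, n),
                   frames=np.arange(n))
        out = cluster_motion(self._rec(t), t, window_events=window)
        floor = 4 * sigma**2 / window
        assert np.mean(out["msd_nm2"][:20]) == pytest.approx(floor, rel=0.25)

    def test_ballistic_motion_msd_quadratic_in_lag(self):
        n, v = 2000, 2.0  # nm per frame, negligible noise
        frames = np.arange(n)
        t = _table(v * frames, np.zeros(n), frames=frames)
        out = cluster_motion(self._rec(t), t, window_events=10)
        lags_frames = out["lags_ms"] / t.frame_time_ms
        expected = (v * lags_frames) ** 2
        np.testing.assert_allclose(out["msd_nm2"][:30], expected[:30], rtol=0.05)

    def test_single_window_returns_flagged_empty(self):
        t = _table(np.zeros(8), np.zeros(8), frames=np.arange(8))
        out = cluster_motion(self._rec(t), t, window_events=10)
        assert out["flag"] == "too_few_events"
        assert out["msd_nm2"].size == 0
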