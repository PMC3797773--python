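import numpy as np
import pytest

from palmcell import synthetic as syn
from palmcell.cells import (
    CellRecord,
    IntensityProfile,
    assign_clusters_to_cells,
    classify_stage,
    detect_cells,
    detect_septum,
    medial_axis_from_contour,
    membrane_profile,
    refine_contour,
    segment_nucleoids,
)
from palmcell.clustering import ClusterRecord
from palmcell.errors import AmbiguityError


def _match_truth(record, truth_cells):
    return min(
        truth_cells,
        key=lambda t: np.hypot(*(np.asarray(t["center_nm"]) - record.centroid_nm)),
    )


def _cluster(cid, x, y):
    return ClusterRecord(cid, np.array([0]), np.array([x, y]), 1, 0, 0)


class TestSegmentNucleoids:
    def test_blank_image_gives_no_seeds(self):
        assert segment_nucleoids(np.full((50, 50), 100.0), 110.0) == []

    def test_three_separated_cells_give_three_seeds_near_truth(self, three_cell_scene):
        seeds = segment_nucleoids(three_cell_scene["dna"].planes[0], 110.0)
        truth = three_cell_scene["truth"]["cells"]
        assert len(seeds) == 3
        for s in seeds:
            t = min(truth, key=lambda t: np.hypot(*(np.asarray(t["center_nm"]) - s["centroid_nm"])))
            assert np.hypot(*(np.asarray(t["center_nm"]) - s["centroid_nm"])) < 2 * 110.0

    def test_touching_cells_with_separated_nucleoids_give_two_seeds(self):
        # cells in physical contact: membranes fuse into one blob, but the
        # DNA signals stay apart and still seed two cells
        specs = [
            syn.CellSpec(length_nm=2500, width_nm=800, center_nm=(3000.0, 3000.0)),
            syn.CellSpec(length_nm=2500, width_nm=800, center_nm=(5600.0, 3000.0)),
        ]
        scene = syn.gen_cell_scene(specs, seed=1, field_size_nm=(9000.0, 6000.0))
        seeds = segment_nucleoids(scene["dna"].planes[0], 110.0)
        assert len(seeds) == 2


class TestRefineContour:
    def test_seed_on_membrane_ridge_is_fixed_point(self, three_cell_scene):
        truth = three_cell_scene["truth"]["cells"][2]  # vegetative cell
        mem = three_cell_scene["membrane"].planes[0]
        refined, low = refine_contour(truth["contour"], mem, 110.0)
        d = np.abs(refined - truth["contour"][np.argmin(
            np.linalg.norm(truth["contour"][None] - refined[:, None], axis=2), axis=1)])
        assert np.median(np.linalg.norm(d, axis=1)) < 110.0
        assert not low

    def test_shrunken_seed_recovers_membrane_within_one_pixel(self, three_cell_scene):
        truth = three_cell_scene["truth"]["cells"][2]
        mem = three_cell_scene["membrane"].planes[0]
        center = np.asarray(truth["center_nm"])
        shrunk = center + 0.8 * (truth["contour"] - center)
        refined, _ = refine_contour(shrunk, mem, 110.0)
        from shapely.geometry import Point, Polygon

        boundary = Polygon(truth["contour"]).exterior
        dists = [boundary.distance(Point(p)) for p in refined]
        assert np.sqrt(np.mean(np.square(dists))) < 110.0

    def test_uniform_image_sets_low_confidence_flag(self):
        seed = syn.CellSpec(center_nm=(2000.0, 2000.0)).contour()
        _, low = refine_contour(seed, np.full((40, 40), 100.0), 110.0)
        assert low


class TestProfileAndSeptum:
    def test_uniform_image_gives_flat_profile(self):
        contour = syn.CellSpec(center_nm=(2000.0, 2000.0)).contour()
        cell = CellRecord(0, contour)
        cell.medial_axis_nm, cell.length_nm = medial_axis_from_contour(contour, 110.0)
        prof = membrane_profile(cell, np.full((40, 40), 50.0), 110.0)
        assert np.ptp(prof.intensities) == 0.0

    def test_profile_covers_the_medial_axis_length(self, three_cell_scene):
        records = detect_cells(three_cell_scene["dna"], three_cell_scene["membrane"])
        cell = records[0]
        prof = membrane_profile(cell, three_cell_scene["membrane"].planes[0], 110.0)
        assert prof.length_nm == pytest.approx(cell.length_nm, abs=110.0)

    def test_flat_profile_has_no_septum(self):
        prof = IntensityProfile(np.linspace(0, 3000, 60), np.full(60, 100.0))
        assert detect_septum(prof) is None

    def test_pole_only_peaks_rejected_by_margin(self):
        x = np.linspace(0, 1, 60)
        y = 100 + 900 * (np.exp(-((x - 0.02) ** 2) / 0.002) + np.exp(-((x - 0.98) ** 2) / 0.002))
        assert detect_septum(IntensityProfile(x * 3000, y)) is None

    def test_interior_ridge_located_within_two_percent(self):
        x = np.linspace(0, 1, 200)
        y = 100 + 300 * np.exp(-((x - 0.22) ** 2) / 0.001)
        pos = detect_septum(IntensityProfile(x * 3000, y))
        assert pos == pytest.approx(0.22, abs=0.02)

    def test_septum_position_error_within_two_percent_on_scene(self, three_cell_scene):
        records = detect_cells(three_cell_scene["dna"], three_cell_scene["membrane"])
        truth = three_cell_scene["truth"]["cells"]
        for r in records:
            t = _match_truth(r, truth)
            if t["septum_rel_pos"] is None:
                assert r.septum_rel_pos is None
            else:
                err = min(
                    abs(r.septum_rel_pos - t["septum_rel_pos"]),
                    abs(1 - r.septum_rel_pos - t["septum_rel_pos"]),
                )
                assert err <= 0.02


class TestClassifyStage:
    @pytest.mark.parametrize(
        "septum,expected",
        [
            (None, "vegetative_predivisional"),
            (0.50, "dividing"),
            (1 / 3, "dividing"),
            (2 / 3, "dividing"),
            (0.20, "sporulating"),
            (0.80, "sporulating"),
        ],
    )
    def test_three_compartment_rule(self, septum, expected):
        assert classify_stage(septum) == expected

    def test_full_scene_stage_recovery_is_exact(self, three_cell_scene):
        records = detect_cells(three_cell_scene["dna"], three_cell_scene["membrane"])
        truth = three_cell_scene["truth"]["cells"]
        assert len(records) == 3
        for r in records:
            assert r.stage == _match_truth(r, truth)["stage"]

    def test_classification_invariant_to_rotation_and_translation(self):
        base = dict(length_nm=3100, width_nm=800, septum_rel_pos=0.2, septum_openness=0.3)
        scene_a = syn.gen_cell_scene(
            [syn.CellSpec(**base, center_nm=(3000.0, 3000.0))],
            seed=5, field_size_nm=(6500.0, 6500.0))
        scene_b = syn.gen_cell_scene(
            [syn.CellSpec(**base, center_nm=(3600.0, 3100.0), angle_deg=35.0)],
            seed=5, field_size_nm=(7000.0, 7000.0))
        rec_a = detect_cells(scene_a["dna"], scene_a["membrane"])
        rec_b = detect_cells(scene_b["dna"], scene_b["membrane"])
        assert rec_a[0].stage == rec_b[0].stage == "sporulating"


class TestAssignment:
    def _cells(self):
        a = CellRecord(0, syn.CellSpec(center_nm=(2000.0, 2000.0)).contour())
        b = CellRecord(1, syn.CellSpec(center_nm=(8000.0, 2000.0)).contour())
        return [a, b]

    def test_cluster_at_cell_centroid_assigned_there(self):
        cells = self._cells()
        orphans = assign_clusters_to_cells(cells, [_cluster(0, 2000.0, 2000.0)])
        assert cells[0].cluster_ids == [0] and orphans == []

    def test_far_away_cluster_is_orphan(self):
        cells = self._cells()
        orphans = assign_clusters_to_cells(cells, [_cluster(3, 5000.0, 9000.0)])
        assert orphans == [3]

    def test_membrane_bound_cluster_assigned_via_dilation(self):
        cells = self._cells()
        # just outside the contour (half-width 400 + 15 nm), inside +1 sigma_loc
        orphans = assign_clusters_to_cells(
            cells, [_cluster(1, 2000.0, 2415.0)], loc_precision_nm=25.0
        )
        assert cells[0].cluster_ids == [1] and orphans == []

    def test_overlapping_contours_raise_ambiguity(self):
        a = CellRecord(0, syn.CellSpec(center_nm=(2000.0, 2000.0)).contour())
        b = CellRecord(1, syn.CellSpec(center_nm=(2100.0, 2000.0)).contour())
        with pytest.raises(AmbiguityError):
            assign_clusters_to_cells([a, b], [_cluster(0, 2050.0, 2000.0)])

    def test_septum_placed_clusters_fully_assigned_on_scene(self, three_cell_scene):
        records = detect_cells(three_cell_scene["dna"], three_cell_scene["membrane"])
        truth = three_cell_scene["truth"]["cells"]
        clusters = []
        for i, t in enumerate(truth):
            p0, p1 = (np.asarray(p) for p in t["axis_endpoints"])
            s = t["septum_rel_pos"] if t["septum_rel_pos"] is not None else 0.5
            c = p0 + s * (p1 - p0)
            clusters.append(_cluster(i, c[0], c[1]))
        orphans = assign_clusters_to_cells(records, clusters)
        assert orphans == []
        assigned = {cid for r in records for cid in r.cluster_ids}
        assert assigned == {0, 1, 2}
        for r in records:
            t = _match_truth(r, truth)
            expected_cid = truth.index(t)
            assert r.cluster_ids == [expected_cid]
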