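"""Merged-mask removal, geometric filters, EFD+PCA outlier rejection,
reference-circle detection and the full filtering pipeline."""

import warnings

import numpy as np
import pytest

from grapecluster import mask_filtering as mf
from grapecluster import synthetic_data as syn
from grapecluster.mask_io import MaskRecord, encode_rle
from grapecluster.shape_features import contour_metrics

from conftest import circle_contour, disk_mask, ellipse_contour


def record_from_grid(grid, mask_id="m"):
    ys, xs = np.nonzero(grid)
    return MaskRecord(
        mask=encode_rle(grid),
        bbox=(int(xs.min()), int(ys.min()),
              int(xs.max() - xs.min() + 1), int(ys.max() - ys.min() + 1)),
        area=int(grid.sum()),
        predicted_iou=0.95,
        stability_score=0.95,
        mask_id=mask_id,
    )


class TestPairwiseOverlap:
    def test_trivial_cases(self):
        a = disk_mask((40, 40), (15, 15), 8)
        b = disk_mask((40, 40), (30, 30), 5)
        assert mf.pairwise_overlap(a, a) == (1.0, 1.0)
        assert mf.pairwise_overlap(a, b) == (0.0, 0.0)

    def test_half_containment_analytic(self):
        sq = np.zeros((20, 20), bool)
        sq[0:10, 0:10] = True
        half = np.zeros((20, 20), bool)
        half[0:5, 0:10] = True
        iou, cont = mf.pairwise_overlap(sq, half)
        assert iou == pytest.approx(0.5)
        assert cont == pytest.approx(1.0)

    def test_matches_pixel_set_oracle(self, rng):
        for _ in range(100):
            a = rng.random((12, 12)) < 0.5
            b = rng.random((12, 12)) < 0.5
            if not (a.any() and b.any()):
                continue
            sa = {(i, j) for i, j in zip(*np.nonzero(a))}
            sb = {(i, j) for i, j in zip(*np.nonzero(b))}
            iou, cont = mf.pairwise_overlap(a, b)
            assert iou == pytest.approx(len(sa & sb) / len(sa | sb))
            assert cont == pytest.approx(len(sa & sb) / min(len(sa), len(sb)))

    def test_symmetry(self, rng):
        a = rng.random((15, 15)) < 0.4
        b = rng.random((15, 15)) < 0.4
        a[0, 0] = b[1, 1] = True
        assert mf.pairwise_overlap(a, b) == mf.pairwise_overlap(b, a)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            mf.pairwise_overlap(np.zeros((5, 5), bool), np.ones((5, 5), bool))


class TestMergedMaskRemoval:
    def test_union_of_two_berries_removed(self):
        b1 = disk_mask((60, 60), (20, 30), 9)
        b2 = disk_mask((60, 60), (38, 30), 9)
        records = [
            record_from_grid(b1, "b1"),
            record_from_grid(b2, "b2"),
            record_from_grid(b1 | b2, "union"),
        ]
        kept, removed = mf.remove_multiberry_masks(records)
        assert {r.mask_id for r in kept} == {"b1", "b2"}
        assert removed[0][0].mask_id == "union"
        assert "b1" in removed[0][1] and "b2" in removed[0][1]

    def test_disjoint_masks_untouched(self):
        records = [
            record_from_grid(disk_mask((80, 80), (20 + 25 * i, 40), 8), f"b{i}")
            for i in range(3)
        ]
        kept, removed = mf.remove_multiberry_masks(records)
        assert len(kept) == 3 and not removed

    def test_single_child_not_removed(self):
        # partial double-detection: big mask contains only one smaller mask
        big = disk_mask((60, 60), (30, 30), 15)
        small = disk_mask((60, 60), (30, 30), 7)
        kept, removed = mf.remove_multiberry_masks(
            [record_from_grid(big, "big"), record_from_grid(small, "small")]
        )
        assert len(kept) == 2 and not removed

    def test_empty_input(self):
        assert mf.remove_multiberry_masks([]) == ([], [])


def _metrics_pairs(grids, ids):
    from grapecluster.mask_io import mask_to_contour
    from grapecluster.shape_features import smooth_contour

    out = []
    for g, i in zip(grids, ids):
        m = contour_metrics(smooth_contour(mask_to_contour(g)))
        out.append((record_from_grid(g, i), m))
    return out


class TestGeometricFilter:
    def test_reference_circle_removed_by_area(self):
        grids = [disk_mask((400, 400), (60 + 30 * (i % 10), 60 + 30 * (i // 10)), 7)
                 for i in range(40)]
        ids = [f"b{i}" for i in range(40)]
        grids.append(disk_mask((400, 400), (300, 300), 50))
        ids.append("circle")
        kept, removed = mf.geometric_filter(_metrics_pairs(grids, ids))
        assert ("circle", "area") in [(r.mask_id, why) for r, why in removed]
        assert len(kept) == 40

    def test_thin_rachis_removed_by_aspect(self):
        grids = [disk_mask((200, 200), (40 + 25 * i, 100), 8) for i in range(5)]
        ids = [f"b{i}" for i in range(5)]
        rachis = np.zeros((200, 200), bool)
        rachis[95:103, 30:150] = True  # 8 x 120 strip
        grids.append(rachis)
        ids.append("rachis")
        kept, removed = mf.geometric_filter(_metrics_pairs(grids, ids))
        assert [(r.mask_id, why) for r, why in removed] == [("rachis", "aspect")]

    def test_far_stain_removed_by_distance(self):
        grids = [disk_mask((300, 300), (140 + 18 * (i % 5), 120 + 18 * (i // 5)), 7)
                 for i in range(25)]
        ids = [f"b{i}" for i in range(25)]
        grids.append(disk_mask((300, 300), (15, 15), 7))
        ids.append("stain")
        kept, removed = mf.geometric_filter(_metrics_pairs(grids, ids))
        assert [(r.mask_id, why) for r, why in removed] == [("stain", "distance")]

    def test_homogeneous_disks_identity(self):
        grids = [disk_mask((200, 200), (50 + 30 * (i % 4), 50 + 30 * (i // 4)), 8)
                 for i in range(12)]
        kept, removed = mf.geometric_filter(
            _metrics_pairs(grids, [f"b{i}" for i in range(12)])
        )
        assert len(kept) == 12 and not removed

    def test_tiny_scene_uses_fallback_bounds(self):
        grids = [disk_mask((60, 60), (30, 30), 10)]
        with pytest.warns(UserWarning, match="fallback"):
            kept, removed = mf.geometric_filter(_metrics_pairs(grids, ["b0"]))
        assert len(kept) == 1


class TestEFDPCAOutlierRemoval:
    @staticmethod
    def _ellipses_and_stars(n_ell=100, n_star=5, seed=42):
        rng = np.random.default_rng(seed)
        th = np.linspace(0, 2 * np.pi, 90, endpoint=False)
        items = []
        for i in range(n_ell):
            a = rng.uniform(16, 22)
            items.append(
                (f"e{i}", ellipse_contour(a, a * rng.uniform(0.8, 1.0),
                                          n=90, rot=rng.uniform(0, np.pi))
                 * (1 + 0.02 * rng.normal(size=(90, 1))))
            )
        for i in range(n_star):
            spikes = 1 + 0.45 * np.cos(5 * th + rng.uniform(0, 2 * np.pi))
            items.append(
                (f"s{i}", np.column_stack([20 * spikes * np.cos(th),
                                           20 * spikes * np.sin(th)]))
            )
        return [(record_from_grid(np.eye(3, dtype=bool), k), c) for k, c in items]

    def test_stars_removed_ellipses_kept(self):
        kept, removed, log = mf.efd_pca_outlier_removal(self._ellipses_and_stars())
        stars = sum(1 for r, _ in removed if r.mask_id.startswith("s"))
        ellipses = sum(1 for r, _ in removed if r.mask_id.startswith("e"))
        assert stars >= 4
        assert ellipses <= 2

    def test_identical_contours_nothing_removed(self):
        items = [
            (record_from_grid(np.eye(3, dtype=bool), f"c{i}"), circle_contour(10))
            for i in range(15)
        ]
        kept, removed, log = mf.efd_pca_outlier_removal(items)
        assert not removed and len(kept) == 15

    def test_round_counts_monotone_non_increasing(self):
        _, _, log = mf.efd_pca_outlier_removal(self._ellipses_and_stars(seed=7))
        assert all(b <= a for a, b in zip(log, log[1:]))

    def test_small_input_skips_stage_with_warning(self):
        items = [
            (record_from_grid(np.eye(3, dtype=bool), f"c{i}"), circle_contour(10))
            for i in range(5)
        ]
        with pytest.warns(UserWarning, match="skipped"):
            kept, removed, log = mf.efd_pca_outlier_removal(items)
        assert len(kept) == 5 and not removed and log == []


class TestReferenceCircleDetection:
    @staticmethod
    def _removed_with_metrics(contours_ids):
        return [
            (record_from_grid(np.eye(3, dtype=bool), i), contour_metrics(c))
            for i, c in contours_ids
        ]

    def test_scale_recovered_within_2pct(self):
        from grapecluster.mask_io import mask_to_contour
        from grapecluster.shape_features import smooth_contour

        grid = disk_mask((260, 260), (130, 130), 100)  # diameter 200 px
        m = contour_metrics(smooth_contour(mask_to_contour(grid)))
        scale = mf.detect_reference_circle(
            [(record_from_grid(grid, "circ"), m)], known_diameter_mm=50.0
        )
        assert scale == pytest.approx(0.25, rel=0.02)

    def test_no_candidate_warns_and_returns_none(self):
        rect = np.array([[0, 0], [40, 0], [40, 10], [0, 10]], float)
        removed = self._removed_with_metrics([("r", rect)])
        with pytest.warns(UserWarning, match="scale"):
            assert mf.detect_reference_circle(removed, 50.0) is None

    def test_circle_beats_square_of_equal_area(self):
        r = 40
        side = np.sqrt(np.pi) * r
        square = np.array([[0, 0], [side, 0], [side, side], [0, side]])
        removed = self._removed_with_metrics(
            [("square", square), ("circle", circle_contour(r))]
        )
        scale = mf.detect_reference_circle(removed, known_diameter_mm=40.0)
        assert scale == pytest.approx(40.0 / (2 * r), rel=0.01)

    def test_invalid_diameter_raises(self):
        with pytest.raises(ValueError):
            mf.detect_reference_circle([], 0.0)


class TestFilterPipeline:
    def test_synthetic_scene_recovery(self):
        cluster = syn.simulate_cluster_3d(syn.ClusterSpec(seed=5))
        scene = syn.inject_artifacts(syn.render_view(cluster, 0), seed=5)
        records, truth = syn.scene_to_mask_records(scene, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            berries, report, scale = mf.run_filter_pipeline(
                records, known_diameter_mm=35.0
            )
        kept = {b.mask_id for b in berries}
        true_berries = {k for k, v in truth.items() if v == "berry"}
        tp = len(kept & true_berries)
        assert tp / len(kept) >= 0.95  # precision
        assert tp / len(true_berries) >= 0.95  # recall
        assert scale == pytest.approx(35.0 / 140.0, rel=0.02)
        report.check_conservation()

    def test_pure_berry_scene_no_removals(self):
        grids = [disk_mask((200, 200), (50 + 30 * (i % 4), 50 + 30 * (i // 4)), 8)
                 for i in range(12)]
        records = [record_from_grid(g, f"b{i}") for i, g in enumerate(grids)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            berries, report, _ = mf.run_filter_pipeline(records)
        assert report.n_kept == 12
        assert (report.n_removed_overlap, report.n_removed_geometric,
                report.n_removed_efd_pca) == (0, 0, 0)

    def test_report_conservation_always_holds(self):
        for seed in range(3):
            cluster = syn.simulate_cluster_3d(syn.ClusterSpec(seed=seed))
            scene = syn.inject_artifacts(syn.render_view(cluster, 0), seed=seed)
            records, _ = syn.scene_to_mask_records(scene, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, report, _ = mf.run_filter_pipeline(records)
            report.check_conservation()
            assert report.n_input == len(records)

    def test_deterministic_given_records_and_config(self):
        cluster = syn.simulate_cluster_3d(syn.ClusterSpec(seed=2))
        scene = syn.inject_artifacts(syn.render_view(cluster, 0), seed=2)
        records, _ = syn.scene_to_mask_records(scene, seed=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            b1, r1, _ = mf.run_filter_pipeline(records)
            b2, r2, _ = mf.run_filter_pipeline(records)
        assert [b.mask_id for b in b1] == [b.mask_id for b in b2]
        assert r1.removals == r2.removals

    def test_median_color_attached_when_image_given(self):
        grids = [disk_mask((100, 100), (25 + 25 * i, 50), 8) for i in range(3)]
        records = [record_from_grid(g, f"b{i}") for i, g in enumerate(grids)]
        img = np.full((100, 100, 3), (90, 40, 110), dtype=np.uint8)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            berries, _, _ = mf.run_filter_pipeline(records, image=img)
        assert all(b.color is not None for b in berries)
        assert berries[0].color.median_g == 40
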