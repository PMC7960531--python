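"""Diagnosis store, boundary construction, suggestions, overlays, and
fluorescence thresholding."""

import numpy as np
import pytest

from ramanmargin.delineate import (
    DiagnosisRecord,
    DiagnosisStore,
    add_diagnosis,
    build_boundary,
    fluorescence_delineation,
    render_overlay,
    suggest_points,
)
from ramanmargin.plsda import Diagnosis
from ramanmargin.tracking import ProbePose

from oracles import shoelace_area


def make_pose(x, y, mm_per_px=0.5):
    return ProbePose(proximal_px=(x - 80, y), distal_px=(x - 40, y),
                     tip_px=(float(x), float(y)), angle_rad=0.0,
                     mm_per_px=mm_per_px, valid=True)


def make_record(i, x, y, positive, mm_per_px=0.5):
    return DiagnosisRecord(index=i, tip_px=(float(x), float(y)),
                           label="pos" if positive else "neg",
                           score=1.0 if positive else 0.0,
                           positive=positive, mm_per_px=mm_per_px)


class TestStore:
    def test_first_addition_gets_index_one(self):
        store = DiagnosisStore()
        add_diagnosis(store, make_pose(10, 10),
                      Diagnosis("pos", {"pos": 0.9, "neg": 0.1}, True))
        assert len(store) == 1
        assert store.records[0].index == 1

    def test_indices_stay_contiguous(self):
        store = DiagnosisStore()
        for k in range(10):
            add_diagnosis(store, make_pose(10 + k, 10),
                          Diagnosis("neg", {"pos": 0.1, "neg": 0.9}, False))
        assert [r.index for r in store.records] == list(range(1, 11))

    def test_invalid_pose_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            add_diagnosis(DiagnosisStore(), ProbePose.invalid(),
                          Diagnosis("pos", {"pos": 1.0}, True))

    def test_csv_round_trip_preserves_delineation(self, tmp_path):
        store = DiagnosisStore()
        for k, (x, y) in enumerate([(50, 50), (90, 50), (50, 90), (20, 20)], 1):
            store.records.append(make_record(k, x, y, positive=(k <= 3)))
        path = tmp_path / "store.csv"
        store.to_csv(path)
        reloaded = DiagnosisStore.from_csv(path)
        a = build_boundary(store.positive_points, 1.5, 0.5, (120, 120))
        b = build_boundary(reloaded.positive_points, 1.5, 0.5, (120, 120))
        np.testing.assert_array_equal(a.mask, b.mask)
        np.testing.assert_allclose(a.boundary, b.boundary)


class TestBuildBoundary:
    def test_triangle_hull_area_600(self):
        pts = [(0.0, 0.0), (30.0, 0.0), (0.0, 40.0)]
        result = build_boundary(pts, 0.0, 0.5, (100, 100), tip_diameter_mm=0.0)
        assert shoelace_area(result.boundary[:-1]) == pytest.approx(600.0)

    def test_single_point_margin_disk_area(self):
        # 3 mm at 0.5 mm/px → radius 6 px → area ≈ π·36
        result = build_boundary([(50.0, 50.0)], 3.0, 0.5, (100, 100),
                                tip_diameter_mm=0.0)
        assert result.mask.sum() == pytest.approx(np.pi * 36.0, rel=0.05)

    def test_no_positives_gives_empty_mask(self):
        result = build_boundary(np.empty((0, 2)), 3.0, 0.5, (50, 50))
        assert not result.mask.any()
        assert result.boundary.shape == (0, 2)

    def test_two_points_give_capsule(self):
        result = build_boundary([(30.0, 50.0), (70.0, 50.0)], 2.0, 0.5, (100, 100),
                                tip_diameter_mm=0.0)
        # enumeration oracle: pixel centers within 4 px of the segment
        yy, xx = np.mgrid[0:100, 0:100]
        t = np.clip((xx - 30.0) / 40.0, 0.0, 1.0)
        dist = np.hypot(xx - (30.0 + 40.0 * t), yy - 50.0)
        expected = dist < 4.0
        mismatches = result.mask ^ expected
        # disagreement only possible on the capsule boundary itself
        assert mismatches.sum() <= np.count_nonzero(np.abs(dist - 4.0) < 0.05)
        assert result.mask.sum() == pytest.approx(expected.sum(), rel=0.02)

    @pytest.mark.parametrize("margins", [(0.0, 1.5, 3.0)])
    def test_masks_strictly_nested_in_margin(self, margins):
        pts = [(40.0, 40.0), (80.0, 45.0), (60.0, 85.0), (45.0, 70.0)]
        masks = [build_boundary(pts, m, 0.5, (130, 130), tip_diameter_mm=2.1).mask
                 for m in margins]
        for smaller, larger in zip(masks, masks[1:]):
            assert np.all(larger[smaller])          # subset
            assert larger.sum() > smaller.sum()     # strict

    def test_adding_a_positive_never_shrinks_the_mask(self):
        pts = [(40.0, 40.0), (80.0, 45.0), (60.0, 85.0)]
        before = build_boundary(pts, 1.5, 0.5, (130, 130)).mask
        after = build_boundary(pts + [(100.0, 100.0)], 1.5, 0.5, (130, 130)).mask
        assert np.all(after[before])

    def test_boundary_depends_on_point_set_not_order(self):
        pts = [(40.0, 40.0), (80.0, 45.0), (60.0, 85.0), (45.0, 70.0)]
        a = build_boundary(pts, 1.5, 0.5, (130, 130)).mask
        b = build_boundary(pts[::-1], 1.5, 0.5, (130, 130)).mask
        np.testing.assert_array_equal(a, b)

    def test_mask_clipped_to_frame(self):
        result = build_boundary([(5.0, 5.0)], 10.0, 0.5, (30, 30))
        assert result.mask.shape == (30, 30)


class TestSuggestPoints:
    def test_single_positive_yields_ring_at_spacing_radius(self):
        store = DiagnosisStore([make_record(1, 100, 100, True)])
        pts = suggest_points(store, spacing_mm=3.0, mm_per_px=0.5)
        radii = np.hypot(pts[:, 0] - 100, pts[:, 1] - 100)
        np.testing.assert_allclose(radii, 6.0, atol=0.05)
        # arc gaps between neighbours ≈ spacing (6 px)
        angles = np.sort(np.arctan2(pts[:, 1] - 100, pts[:, 0] - 100))
        gaps = np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]])) * 6.0
        np.testing.assert_allclose(gaps, 6.0, rtol=0.2)

    def test_candidates_clear_of_existing_measurements(self):
        store = DiagnosisStore([
            make_record(1, 100, 100, True),
            make_record(2, 112, 100, False),
        ])
        pts = suggest_points(store, spacing_mm=3.0, mm_per_px=0.5)
        for rec in store.records:
            d = np.hypot(pts[:, 0] - rec.tip_px[0], pts[:, 1] - rec.tip_px[1])
            # up to the polygonal approximation of the offset ring
            assert np.all(d >= 6.0 * (1 - 1e-3))

    def test_zero_spacing_rejected(self):
        store = DiagnosisStore([make_record(1, 10, 10, True)])
        with pytest.raises(ValueError, match="spacing"):
            suggest_points(store, spacing_mm=0.0, mm_per_px=0.5)

    def test_no_positives_gives_empty_list(self):
        store = DiagnosisStore([make_record(1, 10, 10, False)])
        assert suggest_points(store, 3.0, 0.5).shape == (0, 2)


class TestRenderOverlay:
    def frame(self):
        return np.full((120, 160, 3), 180, dtype=np.uint8)

    def test_square_count_matches_store(self):
        from skimage.measure import label

        store = DiagnosisStore([
            make_record(1, 20, 20, False), make_record(2, 60, 20, False),
            make_record(3, 100, 20, True), make_record(4, 20, 80, True),
            make_record(5, 60, 80, True),
        ])
        img = render_overlay(self.frame(), store)
        green = (img[..., 1] > 150) & (img[..., 0] < 100) & (img[..., 2] < 100)
        red = (img[..., 0] > 150) & (img[..., 1] < 120) & (img[..., 2] < 120)
        assert label(green).max() == 2
        assert label(red).max() == 3

    def test_empty_store_returns_unchanged_copy(self):
        frame = self.frame()
        out = render_overlay(frame, DiagnosisStore())
        np.testing.assert_array_equal(out, frame)
        assert out is not frame

    def test_rendering_is_deterministic(self):
        store = DiagnosisStore([make_record(1, 40, 40, True),
                                make_record(2, 90, 70, False)])
        result = build_boundary([(40.0, 40.0), (90.0, 40.0), (60.0, 90.0)],
                                1.5, 0.5, (120, 160))
        a = render_overlay(self.frame(), store, result)
        b = render_overlay(self.frame(), store, result)
        np.testing.assert_array_equal(a, b)

    def test_mismatched_mask_shape_rejected(self):
        result = build_boundary([(10.0, 10.0)], 1.0, 0.5, (50, 50))
        with pytest.raises(ValueError, match="size"):
            render_overlay(self.frame(), DiagnosisStore(), result)


class TestFluorescenceDelineation:
    def test_threshold_zero_selects_everything_nonnegative(self):
        img = np.abs(np.random.default_rng(0).normal(size=(20, 20)))
        assert fluorescence_delineation(img, "fixed", 0.0).all()

    def test_fixed_threshold_above_noise_gives_empty_mask(self):
        img = np.random.default_rng(1).normal(0, 1.0, size=(40, 40))
        mask = fluorescence_delineation(img, "fixed", 8.0)
        assert not mask.any()

    def test_auto_threshold_on_flat_image_errors(self):
        with pytest.raises(ValueError, match="flat"):
            fluorescence_delineation(np.ones((10, 10)), "auto")

    def test_bright_region_recovered_with_auto_threshold(self):
        img = np.random.default_rng(2).normal(0, 0.5, size=(60, 60))
        img[20:40, 20:40] += 20.0
        mask = fluorescence_delineation(img, "auto")
        region = np.zeros((60, 60), dtype=bool)
        region[20:40, 20:40] = True
        assert mask[region].mean() >= 0.95
        assert mask[~region].mean() <= 0.05

    def test_multichannel_image_rejected(self):
        with pytest.raises(ValueError, match="single-channel"):
            fluorescence_delineation(np.zeros((5, 5, 3)), "fixed", 1.0)
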