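"""Segmentation and circle-fit oracles: Otsu brute force, mask algebra,
limbus sampling, Kasa fit vs geometric least squares."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import least_squares
from skimage.filters import threshold_otsu

import strabscreen as ss
from strabscreen.iris_segmentation import (BinaryMask, CircleFitError,
                                           SegmentationError, ThresholdError,
                                           fit_circle_lsm, otsu_threshold,
                                           remove_small_components,
                                           sample_limbus_points, to_grayscale)


def brute_force_otsu(gray: np.ndarray) -> int:
    """Exhaustive search over all 255 split points maximizing
    between-class variance (the textbook definition, looped)."""
    hist = np.bincount(gray.ravel(), minlength=256).astype(float)
    n = hist.sum()
    best, best_t = -1.0, 0
    for t in range(255):
        w0 = hist[:t + 1].sum()
        w1 = n - w0
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:t + 1] * np.arange(t + 1)).sum() / w0
        m1 = (hist[t + 1:] * np.arange(t + 1, 256)).sum() / w1
        var = w0 * w1 * (m0 - m1) ** 2
        if var > best:
            best, best_t = var, t
    return best_t


def rasterized_disc(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2


class TestOtsu:
    def test_perfectly_bimodal_split(self):
        img = np.full((10, 10), 200, dtype=np.uint8)
        img[:, :5] = 50
        t = otsu_threshold(img)
        assert 50 <= t < 200
        mask = ss.otsu_mask(np.repeat(img[:, :, None], 3, axis=2))
        np.testing.assert_array_equal(mask.pixels, img == 50)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_on_random_images(self, seed):
        gray = np.random.default_rng(seed).integers(0, 256, (40, 50)).astype(np.uint8)
        assert otsu_threshold(gray) == brute_force_otsu(gray)

    def test_matches_brute_force_and_skimage_on_eye_crop(self, rendered_pair):
        img, truth = rendered_pair
        right, _ = ss.detect_and_extract(img, ss.GroundTruthProvider(truth))
        gray = to_grayscale(right.crop)
        t = otsu_threshold(gray)
        assert t == brute_force_otsu(gray)
        # independent library implementation agrees on this histogram
        assert t == int(threshold_otsu(gray))

    def test_mask_overlaps_truth_iris(self, rendered_pair, default_spec):
        img, truth = rendered_pair
        right, _ = ss.detect_and_extract(img, ss.GroundTruthProvider(truth))
        mask = ss.otsu_mask(right.crop).pixels
        cx, cy = right.to_local(truth.pupil_center_right)
        disc = rasterized_disc(mask.shape, (cx, cy), default_spec.iris_radius)
        iou = (mask & disc).sum() / (mask | disc).sum()
        assert iou >= 0.9

    def test_constant_image_rejected(self):
        with pytest.raises(ThresholdError):
            otsu_threshold(np.full((8, 8), 42, dtype=np.uint8))


class TestHsvMask:
    def test_uniform_crop_all_foreground(self):
        crop = np.full((6, 6, 3), 131, dtype=np.uint8)
        assert ss.hsv_mask(crop).pixels.all()  # inclusive upper bound v = 131

    def test_equal_area_bimodal_selects_dark_half(self):
        crop = np.full((10, 10, 3), 200, dtype=np.uint8)
        crop[:5] = 40  # mean = 120 => only the 40-gray half passes
        mask = ss.hsv_mask(crop)
        np.testing.assert_array_equal(mask.pixels, crop[:, :, 0] == 40)

    def test_single_dark_pixel_on_white(self):
        crop = np.full((16, 16, 3), 255, dtype=np.uint8)
        crop[3, 4] = 0
        mask = ss.hsv_mask(crop)
        assert mask.pixels[3, 4]
        assert mask.count() == 1


class TestCombineMasks:
    def test_and_semantics(self):
        rng = np.random.default_rng(0)
        a = BinaryMask(rng.random((12, 9)) > 0.5)
        b = BinaryMask(rng.random((12, 9)) > 0.5)
        combined = ss.combine_masks(a, b)
        np.testing.assert_array_equal(combined.pixels, a.pixels & b.pixels)
        assert combined.count() <= min(a.count(), b.count())
        np.testing.assert_array_equal(ss.combine_masks(a, a).pixels, a.pixels)
        empty = BinaryMask(np.zeros((12, 9), dtype=bool))
        assert ss.combine_masks(a, empty).count() == 0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            ss.combine_masks(BinaryMask(np.ones((3, 3), bool)),
                             BinaryMask(np.ones((4, 3), bool)))


class TestLimbusSampling:
    def test_full_disc_points_on_circle(self):
        mask = BinaryMask(rasterized_disc((60, 60), (30, 28), 20))
        pts = sample_limbus_points(mask)
        radial = np.hypot(pts[:, 0] - 30, pts[:, 1] - 28)
        assert np.all(np.abs(radial - 20) <= 1.0)
        assert np.all(pts[:, 1] >= 28 - 1)  # lower arc only

    def test_occlusion_leaves_lower_arc_unchanged(self):
        full = rasterized_disc((60, 60), (30, 28), 20)
        occluded = full.copy()
        occluded[: int(28 - 20 + 0.4 * 40), :] = False  # clear top 40% rows
        np.testing.assert_array_equal(
            sample_limbus_points(BinaryMask(full)),
            sample_limbus_points(BinaryMask(occluded)))

    def test_single_column_underdetermined(self):
        mask = np.zeros((10, 10), bool)
        mask[2:8, 4] = True
        with pytest.raises(SegmentationError, match="at least 3"):
            sample_limbus_points(BinaryMask(mask))


class TestCircleFit:
    def test_exact_symmetric_circle(self):
        c = fit_circle_lsm([(1, 0), (0, 1), (-1, 0), (0, -1)])
        assert c.center == pytest.approx((0.0, 0.0), abs=1e-9)
        assert c.radius == pytest.approx(1.0, abs=1e-9)
        assert c.rms_residual == pytest.approx(0.0, abs=1e-9)

    def test_three_point_circumcircle(self):
        c = fit_circle_lsm([(0, 0), (2, 0), (0, 2)])
        assert c.center == pytest.approx((1.0, 1.0), abs=1e-9)
        assert c.radius == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_noisy_circle_matches_geometric_oracle(self):
        rng = np.random.default_rng(42)
        theta = rng.uniform(0, 2 * np.pi, 40)
        pts = np.stack([10.0 + 7.0 * np.cos(theta), 5.0 + 7.0 * np.sin(theta)],
                       axis=1) + rng.normal(0, 0.1, (40, 2))
        kasa = fit_circle_lsm(pts)

        def radial(p):
            return np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]) - p[2]

        geom = least_squares(radial, [10.0, 5.0, 7.0]).x
        assert np.hypot(kasa.center[0] - geom[0], kasa.center[1] - geom[1]) <= 0.1
        assert abs(kasa.radius - geom[2]) <= 0.1

    def test_collinear_points_rejected(self):
        with pytest.raises(CircleFitError, match="collinear"):
            fit_circle_lsm([(0, 0), (1, 1), (2, 2), (3, 3)])

    @pytest.mark.parametrize("seed", range(3))
    def test_rigid_motion_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, 2 * np.pi, 25)
        pts = np.stack([3 + 5 * np.cos(theta), -2 + 5 * np.sin(theta)], axis=1)
        pts += rng.normal(0, 0.2, pts.shape)
        base = fit_circle_lsm(pts)
        angle = rng.uniform(0, 2 * np.pi)
        R = np.array([[np.cos(angle), -np.sin(angle)],
                      [np.sin(angle), np.cos(angle)]])
        shift = rng.uniform(-50, 50, 2)
        moved = fit_circle_lsm(pts @ R.T + shift)
        expected_center = R @ np.array(base.center) + shift
        assert moved.center == pytest.approx(tuple(expected_center), rel=1e-9, abs=1e-9)
        assert moved.radius == pytest.approx(base.radius, rel=1e-9)

    @pytest.mark.parametrize("radius", [8, 14, 22, 30, 40])
    def test_rasterized_disc_recovery_grid(self, radius):
        center = (radius + 6.0, radius + 4.0)
        shape = (2 * radius + 14, 2 * radius + 14)
        pts = sample_limbus_points(BinaryMask(rasterized_disc(shape, center, radius)))
        fit = fit_circle_lsm(pts)
        assert np.hypot(fit.center[0] - center[0], fit.center[1] - center[1]) <= 1.0
        assert abs(fit.radius - radius) <= 1.0


class TestEstimatePupilCenter:
    def test_noiseless_fixture_recovery(self, rendered_pair, default_spec):
        img, truth = rendered_pair
        right, left = ss.detect_and_extract(img, ss.GroundTruthProvider(truth))
        for region, center in ((right, truth.pupil_center_right),
                               (left, truth.pupil_center_left)):
            circle = ss.estimate_pupil_center(region.crop)
            est = region.to_face(circle.center)
            assert np.hypot(est[0] - center[0], est[1] - center[1]) <= 1.0
            assert abs(circle.radius - default_spec.iris_radius) <= 1.0

    def test_recovery_under_heavy_occlusion(self, default_spec):
        spec = dataclasses.replace(default_spec, eyelid_occlusion_fraction=0.4)
        img, truth = ss.render_eye_pair(spec)
        right, _ = ss.detect_and_extract(img, ss.GroundTruthProvider(truth))
        circle = ss.estimate_pupil_center(right.crop)
        est = right.to_face(circle.center)
        true = truth.pupil_center_right
        assert np.hypot(est[0] - true[0], est[1] - true[1]) <= 1.0
        assert abs(circle.radius - default_spec.iris_radius) <= 1.0

    def test_uniform_crop_errors(self):
        with pytest.raises(SegmentationError):
            ss.estimate_pupil_center(np.full((30, 30, 3), 99, dtype=np.uint8))

    def test_small_component_cleanup(self):
        mask = np.zeros((50, 50), bool)
        mask[rasterized_disc((50, 50), (25, 25), 15)] = True
        mask[2, 2] = True  # 1-px eyelash speck
        cleaned = remove_small_components(BinaryMask(mask))
        assert not cleaned.pixels[2, 2]
        assert cleaned.count() == mask.sum() - 1
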