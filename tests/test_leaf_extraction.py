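import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

import hyperleaf as hl
from hyperleaf import AchromaticError, DetectionError, EmptyMaskError
from hyperleaf.leaf_extraction import score_training_inlier_fraction


class TestSpectralAngle:
    def test_identical_vectors_give_zero(self):
        a = np.array([0.2, 0.5, 0.3])
        assert hl.spectral_angle(a, a) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_vectors_give_half_pi(self):
        assert hl.spectral_angle([1.0, 0.0], [0.0, 1.0]) == pytest.approx(np.pi / 2)

    def test_scale_invariance(self):
        a = np.array([0.2, 0.5, 0.3])
        assert hl.spectral_angle(a, 2 * a) == pytest.approx(0.0, abs=1e-7)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            hl.spectral_angle([0.0, 0.0], [1.0, 1.0])


class TestHyperHue:
    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(v=hnp.arrays(float, 8, elements=st.floats(0.01, 1.0)),
           c=st.floats(-0.5, 0.5), alpha=st.floats(0.1, 5.0))
    def test_achromatic_shift_and_intensity_invariance(self, v, c, alpha):
        base = np.asarray(v)
        if np.ptp(base) < 1e-6:
            base[0] += 0.1
        h = hl.hyper_hue(base)
        np.testing.assert_allclose(hl.hyper_hue(base + c), h, atol=1e-9)
        np.testing.assert_allclose(hl.hyper_hue(alpha * base),
                                   np.sign(alpha) * h, atol=1e-9)

    def test_unit_norm_and_orthogonal_to_ones(self):
        h = hl.hyper_hue([0.1, 0.4, 0.2, 0.9])
        assert np.linalg.norm(h) == pytest.approx(1.0)
        assert h.sum() == pytest.approx(0.0, abs=1e-12)

    def test_constant_pixel_is_achromatic_error(self):
        with pytest.raises(AchromaticError):
            hl.hyper_hue([0.3, 0.3, 0.3])


class TestMarkerDetection:
    def test_exact_target_recovers_planted_region(self, segmentation_run):
        bundle = segmentation_run["bundle"]
        cfg = hl.GeneratorConfig(seed=5, noise_sigma=0.0)
        clean = hl.generate_cube(cfg)
        cube, _ = hl.calibrate_cube(clean.raw, clean.dark, clean.white)
        mask = hl.detect_marker(cube, clean.marker_target, 0.2)
        np.testing.assert_array_equal(mask.mask, bundle.marker_mask)

    def test_zero_threshold_gives_empty_mask(self, segmentation_run):
        cube = segmentation_run["cube"]
        target = segmentation_run["bundle"].marker_target
        assert hl.detect_marker(cube, target, 0.0).n_pixels == 0

    def test_noisy_marker_recovered_without_false_positives(self, segmentation_run):
        bundle = segmentation_run["bundle"]
        mask = segmentation_run["marker"].mask
        recall = (mask & bundle.marker_mask).sum() / bundle.marker_mask.sum()
        assert recall >= 0.99
        assert (mask & ~bundle.marker_mask).sum() == 0

    def test_illumination_scaling_does_not_change_mask(self, segmentation_run):
        cube = segmentation_run["cube"]
        target = segmentation_run["bundle"].marker_target
        brighter = hl.SpectralCube(cube.data * 1.7, cube.wavelengths,
                                   cube.fwhm, calibrated=True)
        m1 = hl.detect_marker(cube, target, 0.2)
        m2 = hl.detect_marker(brighter, target, 0.2)
        np.testing.assert_array_equal(m1.mask, m2.mask)

    def test_wrong_target_length_rejected(self, segmentation_run):
        with pytest.raises(ValueError, match="bands"):
            hl.detect_marker(segmentation_run["cube"], np.ones(3), 0.2)


def rotated_rect_mask(theta_deg, shape=(80, 80), half=(4, 12)):
    rows, cols = np.mgrid[0:shape[0], 0:shape[1]]
    dy, dx = rows - shape[0] / 2, cols - shape[1] / 2
    t = np.deg2rad(theta_deg)
    along = dx * np.cos(t) + dy * np.sin(t)
    across = -dx * np.sin(t) + dy * np.cos(t)
    return (np.abs(along) <= half[1]) & (np.abs(across) <= half[0])


class TestLocateROI:
    def test_axis_aligned_marker_has_zero_orientation(self):
        roi = hl.locate_roi(hl.PixelMask(rotated_rect_mask(0.0)))
        assert min(roi.orientation, np.pi - roi.orientation) < 1e-6

    def test_rotated_marker_orientation_within_one_degree(self):
        roi = hl.locate_roi(hl.PixelMask(rotated_rect_mask(30.0)))
        assert abs(np.rad2deg(roi.orientation) - 30.0) < 1.0

    def test_single_pixel_marker_is_degenerate(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        with pytest.raises(DetectionError, match="degenerate"):
            hl.locate_roi(hl.PixelMask(mask))

    def test_empty_marker_is_detection_failure(self):
        with pytest.raises(DetectionError, match="empty"):
            hl.locate_roi(hl.PixelMask(np.zeros((10, 10), dtype=bool)))


class TestLeafSegmentation:
    def test_training_inlier_fraction_respects_nu(self, segmentation_run):
        frac = score_training_inlier_fraction(segmentation_run["training"], 0.1)
        assert frac >= 1.0 - 0.1 - 0.05

    def test_leaf_mask_iou_against_planted_truth(self, segmentation_run):
        leaf = segmentation_run["leaf"].mask
        truth = segmentation_run["bundle"].leaf_mask
        iou = (leaf & truth).sum() / (leaf | truth).sum()
        assert iou >= 0.95

    def test_all_background_roi_yields_almost_nothing(self, segmentation_run):
        cube = segmentation_run["cube"]
        roi = hl.LeafBedROI((8.0, 8.0), 0.0, (10.0, 14.0))  # empty corner
        mask = hl.segment_leaf(cube, roi, segmentation_run["training"], nu=0.1)
        assert mask.n_pixels < 0.01 * cube.data.shape[0] * cube.data.shape[1]

    def test_too_few_training_pixels_rejected(self, segmentation_run):
        with pytest.raises(ValueError, match="training"):
            hl.segment_leaf(segmentation_run["cube"], segmentation_run["roi"],
                            segmentation_run["training"][:5])


class TestMeanSignature:
    def test_identical_pixels_return_that_signature(self):
        data = np.tile(np.array([0.1, 0.2, 0.3]), (4, 4, 1))
        cube = hl.SpectralCube(data, [400.0, 500.0, 600.0], 1.0)
        mask = hl.PixelMask(np.ones((4, 4), dtype=bool))
        np.testing.assert_allclose(hl.mean_signature(cube, mask, "A").values,
                                   [0.1, 0.2, 0.3])

    def test_two_pixel_midpoint(self):
        data = np.zeros((1, 2, 2))
        data[0, 0] = [0.2, 0.2]
        data[0, 1] = [0.4, 0.4]
        cube = hl.SpectralCube(data, [400.0, 500.0], 1.0)
        mask = hl.PixelMask(np.ones((1, 2), dtype=bool))
        np.testing.assert_allclose(hl.mean_signature(cube, mask, "A").values, 0.3)

    def test_mean_bounded_by_pixel_extremes(self, segmentation_run):
        cube = segmentation_run["cube"]
        mask = segmentation_run["leaf"]
        mean = hl.mean_signature(cube, mask, "A").values
        pixels = cube.data[mask.mask]
        assert np.all(mean >= pixels.min(axis=0) - 1e-12)
        assert np.all(mean <= pixels.max(axis=0) + 1e-12)

    def test_empty_mask_is_acquisition_error(self, segmentation_run):
        empty = hl.PixelMask(np.zeros(segmentation_run["cube"].shape[:2],
                                      dtype=bool))
        with pytest.raises(EmptyMaskError):
            hl.mean_signature(segmentation_run["cube"], empty, "A")


class TestMergeVnirSwir:
    def make_pair(self, offset):
        vn_lam = np.arange(400.0, 1000.1, 5.5)
        sw_lam = np.arange(1000.0, 1500.1, 12.0)
        trend = lambda lam: 0.1 + 2e-4 * lam  # noqa: E731
        vn = hl.Spectrum("L", vn_lam, trend(vn_lam), 5.5, "fx10")
        sw = hl.Spectrum("L", sw_lam, trend(sw_lam) + offset, 12.0, "swir")
        return vn, sw

    def test_offset_segment_made_continuous(self):
        vn, sw = self.make_pair(0.05)
        merged = hl.merge_vnir_swir(vn, sw)
        lam = merged.wavelengths
        np.testing.assert_allclose(merged.values, 0.1 + 2e-4 * lam, atol=1e-9)
        assert len(merged.detector_segments) == 2

    def test_zero_offset_keeps_concatenation(self):
        vn, sw = self.make_pair(0.0)
        merged = hl.merge_vnir_swir(vn, sw)
        keep = sw.wavelengths > vn.wavelengths[-1] + 1e-6
        np.testing.assert_allclose(
            merged.values, np.concatenate([vn.values, sw.values[keep]]),
            atol=1e-9)

    def test_duplicate_boundary_band_dropped_from_swir(self):
        vn_lam = np.arange(400.0, 1000.5, 5.0)   # ends exactly at 1000
        sw_lam = np.arange(1000.0, 1200.5, 12.0)  # starts exactly at 1000
        vn = hl.Spectrum("L", vn_lam, np.full(vn_lam.size, 0.3), 5.5)
        sw = hl.Spectrum("L", sw_lam, np.full(sw_lam.size, 0.3), 12.0)
        merged = hl.merge_vnir_swir(vn, sw)
        assert (merged.wavelengths == 1000.0).sum() == 1
        assert merged.fwhm[merged.wavelengths == 1000.0][0] == 5.5  # VNIR wins

    def test_fwhm_metadata_preserved_per_segment(self):
        vn, sw = self.make_pair(0.02)
        merged = hl.merge_vnir_swir(vn, sw)
        (a, b), (c, d) = merged.detector_segments
        assert np.all(merged.fwhm[a:b] == 5.5)
        assert np.all(merged.fwhm[c:d] == 12.0)

    def test_interleaved_grids_rejected(self):
        vn, _ = self.make_pair(0.0)
        sw = hl.Spectrum("L", np.arange(300.0, 600.0, 12.0),
                         np.full(25, 0.3), 12.0)
        with pytest.raises(ValueError):
            hl.merge_vnir_swir(vn, sw)


class TestEndToEndRecovery:
    def test_recovered_mean_signature_within_noise_standard_error(
            self, segmentation_run):
        bundle = segmentation_run["bundle"]
        cube = segmentation_run["cube"]
        leaf = segmentation_run["leaf"]
        recovered = hl.smooth(hl.mean_signature(cube, leaf, "A"))
        planted = hl.smooth(hl.Spectrum(
            "truth", cube.wavelengths,
            bundle.planted_reflectance[leaf.mask].mean(axis=0), cube.fwhm))
        bound = 3.0 * bundle.noise_sigma / np.sqrt(leaf.n_pixels)
        assert np.max(np.abs(recovered.values - planted.values)) <= bound
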