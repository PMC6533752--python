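"""Fiber extraction: preprocessing, binarization, ridge tracing, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibergrade.evaluation import match_to_ground_truth
from fibergrade.fibers import (
    ExtractionConfig,
    FiberTrace,
    binarize,
    extract_fibers,
    fiber_mask,
    filter_valid_fibers,
    foreground_fraction,
    preprocess,
)
from fibergrade.synthetic import (
    Fiber,
    FiberGroundTruth,
    SyntheticSpec,
    blank_ground_truth,
    render_shg_image,
)

CFG = ExtractionConfig()


def straight_trace(length_um, angle_deg=0.0):
    """Minimal FiberTrace of a given length for filter tests."""
    px = length_um / CFG.pixel_size_um
    d = np.array([np.cos(np.deg2rad(angle_deg)), np.sin(np.deg2rad(angle_deg))])
    pts = np.array([[10.0, 10.0], [10.0, 10.0] + d * px])
    return FiberTrace(pts, length_um, angle_deg % 180.0, 1.0)


class TestPreprocess:
    def test_constant_image_maps_to_zero(self):
        out = preprocess(np.full((64, 64), 37.0), CFG)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_ridge_peak_position_preserved(self, single_fiber_image):
        _, img = single_fiber_image
        out = preprocess(img, CFG)
        row_raw = int(np.argmax(img[:, 64]))
        row_pre = int(np.argmax(out[:, 64]))
        assert abs(row_raw - row_pre) <= 0.5

    def test_pure_noise_yields_almost_no_foreground(self):
        spec = SyntheticSpec(image_size_px=(256, 256), seed=12)
        noise = render_shg_image(blank_ground_truth(spec))
        assert foreground_fraction(noise, CFG) < 0.01


class TestBinarize:
    def test_binary_image_recovered_for_any_fixed_threshold(self):
        img = np.zeros((20, 20))
        img[5:10, 5:10] = 255.0
        for t in (1.0, 100.0, 254.0):
            mask = binarize(img, "fixed", threshold=t)
            np.testing.assert_array_equal(mask, img == 255)

    def test_zero_threshold_keeps_all_positive_pixels(self):
        img = np.full((10, 10), 50.0)
        assert binarize(img, "fixed", threshold=0.0).all()

    def test_constant_image_otsu_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = binarize(np.full((16, 16), 3.0), "otsu")
        assert not mask.any()

    def test_blank_core_below_no_signal_threshold(self):
        spec = SyntheticSpec(image_size_px=(400, 400), seed=31)
        blank = render_shg_image(blank_ground_truth(spec))
        assert foreground_fraction(blank, CFG) < 0.001

    def test_fixed_method_requires_threshold(self):
        with pytest.raises(ValueError, match="threshold"):
            binarize(np.zeros((4, 4)), "fixed")


class TestExtractFibers:
    def test_single_fiber_recovered(self, single_fiber_image):
        truth, img = single_fiber_image
        fibers = extract_fibers(preprocess(img, CFG), CFG)
        assert len(fibers) == 1
        f = fibers[0]
        assert f.length_um == pytest.approx(80 * CFG.pixel_size_um, rel=0.10)
        assert min(f.orientation_deg, 180 - f.orientation_deg) < 2.0

    def test_two_parallel_fibers_kept_separate(self):
        spec = SyntheticSpec(
            image_size_px=(128, 128), background_level=0.0,
            poisson_scale=0.0, gaussian_read_sd=0.0, seed=0,
        )
        fibers = (
            Fiber(np.array([[20.0, 40.0], [100.0, 40.0]]), 0.0, 80 * CFG.pixel_size_um),
            Fiber(np.array([[20.0, 90.0], [100.0, 90.0]]), 0.0, 80 * CFG.pixel_size_um),
        )
        img = render_shg_image(FiberGroundTruth(fibers, spec), noise=False)
        out = extract_fibers(preprocess(img, CFG), CFG)
        assert len(out) == 2
        for f in out:
            assert min(f.orientation_deg, 180 - f.orientation_deg) < 2.0

    def test_empty_foreground_gives_empty_list(self):
        assert extract_fibers(np.zeros((64, 64)), CFG) == []

    def test_rotation_equivariance_90_degrees(self, sparse_roi):
        _, img = sparse_roi
        a = extract_fibers(preprocess(img, CFG), CFG)
        b = extract_fibers(preprocess(np.rot90(img), CFG), CFG)
        med_a = np.median([f.orientation_deg for f in a])
        med_b = np.median([f.orientation_deg for f in b])
        diff = abs(med_a - med_b) % 180.0
        assert abs(min(diff, 180 - diff) - 90.0) < 4.0 or len(a) != len(b)
        # counts should agree closely too
        assert abs(len(a) - len(b)) <= max(2, 0.1 * len(a))

    def test_translation_invariance(self, single_fiber_image):
        _, img = single_fiber_image
        shifted = np.roll(img, (7, 11), axis=(0, 1))
        a = extract_fibers(preprocess(img, CFG), CFG)
        b = extract_fibers(preprocess(shifted, CFG), CFG)
        assert len(a) == len(b) == 1
        assert b[0].length_um == pytest.approx(a[0].length_um, rel=0.05)
        np.testing.assert_allclose(
            b[0].centerline.mean(axis=0) - a[0].centerline.mean(axis=0),
            [11, 7],
            atol=1.5,
        )

    def test_length_matches_centerline_arc_length(self, sparse_roi):
        _, img = sparse_roi
        for f in extract_fibers(preprocess(img, CFG), CFG):
            arc = np.sum(np.hypot(*np.diff(f.centerline, axis=0).T))
            assert f.length_um == pytest.approx(arc * CFG.pixel_size_um, rel=1e-6)

    def test_recovery_on_sparse_field(self, sparse_roi):
        truth, img = sparse_roi
        valid = filter_valid_fibers(extract_fibers(preprocess(img, CFG), CFG), CFG)
        stats = match_to_ground_truth(valid, truth)
        assert stats.precision >= 0.85 and stats.recall >= 0.85


class TestFilterValidFibers:
    def test_printed_threshold_examples(self):
        fibers = [straight_trace(l) for l in (4.0, 6.0, 10.0)]
        assert len(filter_valid_fibers(fibers, CFG)) == 2
        assert filter_valid_fibers([straight_trace(5.3)], CFG) == []
        short = [straight_trace(l) for l in (1.0, 5.0, 5.3)]
        assert filter_valid_fibers(short, CFG) == []

    def test_zero_threshold_is_identity(self):
        fibers = [straight_trace(l) for l in (0.5, 2.0, 9.0)]
        assert filter_valid_fibers(fibers, min_length_um=0.0) == fibers

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.01, max_value=60.0), max_size=40))
    def test_equals_bruteforce_length_filter(self, lengths):
        fibers = [straight_trace(l) for l in lengths]
        expected = [f for f in fibers if f.length_um > 5.3]
        assert filter_valid_fibers(fibers, CFG) == expected
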