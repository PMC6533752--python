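"""Registration: K-means segmentation, landmark and intensity estimation,
ROI mapping between H&E and SHG pixel grids."""

import numpy as np
import pytest

from fibergrade.model import ROIAnnotation
from fibergrade.registration import (
    IntensityRegistrationSettings,
    LandmarkPairSet,
    register_he_to_shg,
    register_intensity,
    register_landmarks,
    segment_he_kmeans,
    transform_roi,
    _warp,
)
from fibergrade.transforms import AffineTransform2D

HE_UM = 0.505
SHG_UM = 0.1767


@pytest.fixture(scope="module")
def shg_pair():
    """Smoothed SHG image for self-registration tests."""
    import scipy.ndimage as ndi

    from fibergrade.synthetic import SyntheticSpec, render_shg_image, sample_fiber_population

    spec = SyntheticSpec(image_size_px=(400, 400), fiber_count_mean=120, seed=5)
    img = render_shg_image(sample_fiber_population(spec))
    return ndi.gaussian_filter(img.astype(float), 3.0)


class TestSegmentation:
    def test_two_color_disk_segmented_exactly(self):
        img = np.full((120, 120, 3), 255, dtype=np.uint8)
        yy, xx = np.mgrid[0:120, 0:120]
        disk = (xx - 60) ** 2 + (yy - 60) ** 2 <= 40**2
        img[disk] = (230, 120, 170)
        _, tissue = segment_he_kmeans(img, k=2, seed=0)
        np.testing.assert_array_equal(tissue, disk)

    def test_all_white_image_gives_empty_mask(self):
        img = np.full((50, 50, 3), 255, dtype=np.uint8)
        with pytest.warns(UserWarning):
            _, tissue = segment_he_kmeans(img, k=3, seed=0)
        assert not tissue.any()

    def test_pseudo_he_tissue_covered(self):
        from fibergrade.synthetic import SyntheticSpec, render_pseudo_he_image, sample_fiber_population

        spec = SyntheticSpec(image_size_px=(400, 400), fiber_count_mean=80, seed=6)
        truth = sample_fiber_population(spec)
        he = render_pseudo_he_image(truth, AffineTransform2D.identity())
        _, tissue = segment_he_kmeans(he, k=3, seed=0)
        # ground-truth footprint: unambiguously tissue-colored pixels
        # (brighter values are the anti-aliased rim of the core footprint)
        truth_fg = he.mean(axis=-1) < 230
        assert (tissue & truth_fg).sum() / truth_fg.sum() >= 0.99


class TestLandmarks:
    def test_exact_affine_interpolation(self):
        t_true = AffineTransform2D(np.array([[1.2, 0.1, 5.0], [-0.2, 0.9, -3.0], [0, 0, 1]]))
        src = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        pairs = LandmarkPairSet(src, t_true.apply(src))
        est = register_landmarks(pairs, "affine")
        np.testing.assert_allclose(est.matrix, t_true.matrix, atol=1e-9)
        assert est.meta["residual_rms"] < 1e-9

    def test_perturbed_pairs_match_normal_equations(self):
        t_true = AffineTransform2D(np.array([[1.1, 0.0, 2.0], [0.0, 1.1, -1.0], [0, 0, 1]]))
        src = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]])
        dst = t_true.apply(src)
        dst[0] += (0.5, -0.3)
        est = register_landmarks(LandmarkPairSet(src, dst), "affine")
        # independent oracle: solve the least-squares normal equations directly
        A = np.hstack([src, np.ones((4, 1))])
        coef, *_ = np.linalg.lstsq(A, dst, rcond=None)
        expected = np.vstack([coef.T, [0, 0, 1]])
        np.testing.assert_allclose(est.matrix, expected, atol=1e-9)
        assert est.meta["residual_rms"] > 0

    def test_underdetermined_and_collinear_rejected(self):
        two = LandmarkPairSet([[0.0, 0.0], [1.0, 1.0]], [[0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="pairs"):
            register_landmarks(two, "affine")
        collinear = LandmarkPairSet(
            [[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]],
            [[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]],
        )
        with pytest.raises(ValueError, match="collinear"):
            register_landmarks(collinear, "affine")

    def test_similarity_recovers_generating_transform(self):
        t_true = AffineTransform2D.similarity(1.3, 25.0, (4.0, -2.0))
        src = np.array([[0.0, 0.0], [20.0, 5.0], [3.0, 17.0], [11.0, 9.0]])
        est = register_landmarks(LandmarkPairSet(src, t_true.apply(src)), "similarity")
        np.testing.assert_allclose(est.matrix, t_true.matrix, atol=1e-9)


class TestIntensityRegistration:
    def test_self_registration_is_identity(self, shg_pair):
        for model in ("translation", "rigid", "similarity"):
            res = register_intensity(shg_pair, shg_pair, model=model)
            err = np.abs(res.transform.matrix - np.eye(3)).max()
            assert err < 0.1, model
            assert res.converged

    def test_known_translation_recovered(self, shg_pair):
        t_true = AffineTransform2D.translation(12.0, -7.0)
        moving = _warp(shg_pair, t_true.inverse(), shg_pair.shape)
        res = register_intensity(shg_pair, moving, model="translation")
        np.testing.assert_allclose(res.transform.offset, (12.0, -7.0), atol=1.0)

    def test_known_rigid_recovered(self, shg_pair):
        c = (199.5, 199.5)
        t_true = AffineTransform2D.similarity(1.0, 5.0, (8.0, -4.0), center=c)
        moving = _warp(shg_pair, t_true.inverse(), shg_pair.shape)
        res = register_intensity(shg_pair, moving, model="rigid")
        assert abs(res.transform.rotation_deg - 5.0) < 1.0
        err = np.linalg.norm(res.transform.apply([c])[0] - t_true.apply([c])[0])
        assert err < 1.0


class TestFullCoreRegistration:
    def test_roi_centers_mapped_within_two_pixels(self):
        from fibergrade.synthetic import (
            SyntheticSpec,
            render_pseudo_he_image,
            render_shg_image,
            sample_fiber_population,
            true_he_to_shg_transform,
        )

        spec = SyntheticSpec(image_size_px=(400, 400), fiber_count_mean=120, seed=8)
        truth = sample_fiber_population(spec)
        shg = render_shg_image(truth)
        ratio = SHG_UM / HE_UM
        he_c = ((400 * ratio - 1) / 2,) * 2
        offset = AffineTransform2D.similarity(1.0, -1.5, (4.0, 1.0), center=he_c)
        he = render_pseudo_he_image(truth, offset)
        t_true = true_he_to_shg_transform(spec, offset)
        res = register_he_to_shg(shg, he, SHG_UM, HE_UM, seed=0)
        assert res.converged
        for c in ([70.0, 70.0], [50.0, 90.0], [90.0, 50.0]):
            err = np.linalg.norm(res.transform.apply([c])[0] - t_true.apply([c])[0])
            assert err <= 2.0

    def test_blank_he_flags_non_convergence(self):
        shg = np.zeros((100, 100))
        he = np.full((35, 35, 3), 255, dtype=np.uint8)
        with pytest.warns(UserWarning):
            res = register_he_to_shg(shg, he, SHG_UM, HE_UM, seed=0)
        assert not res.converged


class TestTransformRoi:
    def test_identity_with_equal_pixel_sizes(self):
        roi = ROIAnnotation("r", 10, 20, 110, 140, space="he")
        out = transform_roi(roi, AffineTransform2D.identity(), scales=(1.0, 1.0))
        assert (out.x0, out.y0, out.x1, out.y1) == (10, 20, 110, 140)
        assert out.space == "shg"
        assert out.meta["shift_px"] == pytest.approx(0.0)

    def test_pixel_size_ratio_scales_roi(self):
        roi = ROIAnnotation("r", 0, 0, 400, 400, space="he")
        t = AffineTransform2D.scaling(HE_UM / SHG_UM)
        out = transform_roi(roi, t)
        assert out.width == pytest.approx(1143, abs=2)
        assert out.height == pytest.approx(1143, abs=2)

    def test_rotation_by_90_swaps_width_and_height(self):
        roi = ROIAnnotation("r", 0, 0, 100, 40, space="he")
        t = AffineTransform2D.similarity(1.0, 90.0, (0.0, 0.0), center=(50.0, 20.0))
        out = transform_roi(roi, t)
        assert (out.width, out.height) == (roi.height, roi.width)

    def test_round_trip_contains_original(self):
        roi = ROIAnnotation("r", 5, 7, 45, 67, space="he")
        t = AffineTransform2D.similarity(2.9, 13.0, (3.3, -1.2), center=(25.0, 37.0))
        fwd = transform_roi(roi, t)
        back = transform_roi(
            ROIAnnotation("r", fwd.x0, fwd.y0, fwd.x1, fwd.y1, space="he"), t.inverse()
        )
        assert back.x0 <= roi.x0 and back.y0 <= roi.y0
        assert back.x1 >= roi.x1 and back.y1 >= roi.y1

    def test_roi_outside_image_rejected(self):
        roi = ROIAnnotation("r", 0, 0, 10, 10, space="he")
        t = AffineTransform2D.translation(500.0, 500.0)
        with pytest.raises(Exception, match="outside"):
            transform_roi(roi, t, shg_shape=(100, 100))
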