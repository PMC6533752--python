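"""Ground-truth generator: sampling distributions, rendering, cohorts."""

import numpy as np
import pytest
from scipy.special import i0e, i1e

from fibergrade.synthetic import (
    CohortSpec,
    SpecValidationError,
    SyntheticSpec,
    blank_ground_truth,
    generate_cohort,
    render_pseudo_he_image,
    render_shg_image,
    sample_axial_orientations,
    sample_fiber_population,
)
from fibergrade.transforms import AffineTransform2D


def doubled_resultant(theta_deg):
    d = np.deg2rad(2.0 * np.asarray(theta_deg))
    return np.hypot(np.cos(d).sum(), np.sin(d).sum()) / len(d)


class TestOrientationSampling:
    def test_uniform_when_kappa_zero(self):
        theta = sample_axial_orientations(10_000, 45.0, 0.0, np.random.default_rng(1))
        assert doubled_resultant(theta) < 0.03  # E[R] ~ 1/sqrt(n) under uniformity

    def test_degenerate_at_large_kappa(self):
        theta = sample_axial_orientations(500, 73.0, 1e6, np.random.default_rng(2))
        assert np.all(np.abs(theta - 73.0) < 0.1)

    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 5.0])
    def test_resultant_matches_bessel_ratio(self, kappa):
        """Sample R of doubled angles estimates I1(kappa)/I0(kappa)."""
        n = 10_000
        theta = sample_axial_orientations(n, 30.0, kappa, np.random.default_rng(3))
        expected = i1e(kappa) / i0e(kappa)
        # delta-method SE of the mean resultant length
        from scipy.special import ive

        a2 = float(ive(2, kappa) / i0e(kappa))
        se = np.sqrt(max((1 + a2) / 2 - expected**2, 1e-12) / n)
        assert abs(doubled_resultant(theta) - expected) < 3 * se + 1e-3


class TestFiberPopulation:
    def test_deterministic_given_seed(self):
        spec = SyntheticSpec(image_size_px=(256, 256), fiber_count_mean=30, seed=7)
        a = sample_fiber_population(spec)
        b = sample_fiber_population(spec)
        assert len(a.fibers) == len(b.fibers)
        for fa, fb in zip(a.fibers, b.fibers):
            np.testing.assert_array_equal(fa.points, fb.points)

    def test_centerlines_within_bounds(self):
        spec = SyntheticSpec(image_size_px=(128, 200), fiber_count_mean=60, seed=3)
        truth = sample_fiber_population(spec)
        for f in truth.fibers:
            assert np.all(f.points[:, 0] >= 0) and np.all(f.points[:, 0] <= 199)
            assert np.all(f.points[:, 1] >= 0) and np.all(f.points[:, 1] <= 127)

    def test_orientation_is_axial_angle_of_end_to_end_vector(self):
        spec = SyntheticSpec(image_size_px=(256, 256), fiber_count_mean=40, seed=11)
        truth = sample_fiber_population(spec)
        for f in truth.fibers:
            v = f.points[-1] - f.points[0]
            ang = np.mod(np.rad2deg(np.arctan2(v[1], v[0])), 180.0)
            assert abs(ang - f.orientation_deg) < 1e-9 or abs(abs(ang - f.orientation_deg) - 180) < 1e-9

    @pytest.mark.parametrize(
        "field,value",
        [("orientation_kappa", -1.0), ("image_size_px", (0, 10)), ("fiber_width_um", 0.0)],
    )
    def test_invalid_spec_names_field(self, field, value):
        spec = SyntheticSpec(**{field: value})
        with pytest.raises(SpecValidationError, match=field.split("_")[0]):
            sample_fiber_population(spec)


class TestRenderShg:
    def test_zero_fibers_no_background_renders_black(self):
        spec = SyntheticSpec(
            image_size_px=(64, 64), background_level=0.0, poisson_scale=0.0,
            gaussian_read_sd=0.0, seed=0,
        )
        img = render_shg_image(blank_ground_truth(spec), noise=False)
        assert np.all(img == 0)

    def test_single_fiber_profile_and_mass(self, single_fiber_image):
        truth, img = single_fiber_image
        # row profile peaks at the fiber's row
        assert abs(int(np.argmax(img.sum(axis=1))) - 64) <= 1
        # total intensity proportional to length: compare to a half-length fiber
        from fibergrade.synthetic import Fiber, FiberGroundTruth

        half = Fiber(
            points=np.array([[44.0, 64.0], [84.0, 64.0]]),
            orientation_deg=0.0,
            length_um=40 * truth.spec.shg_pixel_size_um,
        )
        img_half = render_shg_image(FiberGroundTruth((half,), truth.spec), noise=False)
        assert img.sum() == pytest.approx(2.0 * img_half.sum(), rel=0.02)

    def test_total_intensity_monotone_in_fiber_count(self):
        totals = []
        for count in (5, 20, 60):
            spec = SyntheticSpec(
                image_size_px=(256, 256), fiber_count_mean=count,
                background_level=0.0, seed=5,
            )
            truth = sample_fiber_population(spec)
            totals.append(render_shg_image(truth, noise=False).sum())
        assert totals[0] < totals[1] < totals[2]

    def test_noise_free_render_reproducible(self, sparse_roi):
        truth, _ = sparse_roi
        a = render_shg_image(truth, noise=False)
        b = render_shg_image(truth, noise=False)
        np.testing.assert_array_equal(a, b)

    def test_noisy_render_reproducible_given_seed(self, sparse_roi):
        truth, _ = sparse_roi
        a = render_shg_image(truth, np.random.default_rng(9))
        b = render_shg_image(truth, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)


class TestRenderHe:
    def test_blank_core_renders_white(self):
        spec = SyntheticSpec(image_size_px=(200, 200), seed=0)
        he = render_pseudo_he_image(blank_ground_truth(spec), AffineTransform2D.identity())
        assert np.all(he == 255)

    def test_singular_offset_rejected(self, sparse_roi):
        truth, _ = sparse_roi
        singular = AffineTransform2D(np.array([[0.0, 0, 0], [0, 0, 0], [0, 0, 1]]))
        with pytest.raises(SpecValidationError, match="singular"):
            render_pseudo_he_image(truth, singular)

    def test_he_shape_follows_pixel_size_ratio(self, sparse_roi):
        truth, _ = sparse_roi
        he = render_pseudo_he_image(truth, AffineTransform2D.identity())
        ratio = truth.spec.shg_pixel_size_um / truth.spec.he_pixel_size_um
        assert he.shape[:2] == (int(np.ceil(400 * ratio)),) * 2


class TestCohorts:
    @pytest.fixture(scope="class")
    def tiny_cohort(self, tmp_path_factory):
        out = tmp_path_factory.mktemp("cohort")
        spec = CohortSpec(
            n_cores_per_group=(3, 2),
            rois_per_core=2,
            group_specs=(
                SyntheticSpec(image_size_px=(300, 300), fiber_count_mean=40),
                SyntheticSpec(image_size_px=(300, 300), fiber_count_mean=90),
            ),
            n_blank_cores_per_group=(1, 0),
            roi_size_he_px=60,
            seed=42,
        )
        manifest = generate_cohort(spec, out, render_he=False)
        return spec, out, manifest

    def test_core_and_blank_counts(self, tiny_cohort):
        _, _, manifest = tiny_cohort
        cores = manifest["cores"]
        assert sum(c["grade"] == "grade1" for c in cores) == 3
        assert sum(c["grade"] == "grade4" for c in cores) == 2
        assert sum(c["blank"] for c in cores) == 1

    def test_patient_ids_distinct(self, tiny_cohort):
        _, _, manifest = tiny_cohort
        pids = [c["patient_id"] for c in manifest["cores"]]
        assert len(set(pids)) == len(pids)

    def test_ground_truth_tables_written(self, tiny_cohort):
        import pandas as pd

        _, out, _ = tiny_cohort
        fibers = pd.read_csv(out / "ground_truth_fibers.csv")
        rois = pd.read_csv(out / "ground_truth_rois.csv")
        assert len(rois) == 5 * 2
        assert {"core_id", "orientation_deg", "length_um"} <= set(fibers.columns)
        assert fibers["core_id"].nunique() == 4  # blank core has no fibers

    def test_distinct_seeds_give_disjoint_fiber_tables(self, tmp_path):
        spec1 = CohortSpec(
            n_cores_per_group=(1, 1), rois_per_core=2,
            group_specs=(SyntheticSpec(image_size_px=(200, 200), fiber_count_mean=25),) * 2,
            roi_size_he_px=40, seed=1,
        )
        import dataclasses
        import pandas as pd

        spec2 = dataclasses.replace(spec1, seed=2)
        generate_cohort(spec1, tmp_path / "a", render_he=False)
        generate_cohort(spec2, tmp_path / "b", render_he=False)
        fa = pd.read_csv(tmp_path / "a" / "ground_truth_fibers.csv")
        fb = pd.read_csv(tmp_path / "b" / "ground_truth_fibers.csv")
        merged = fa.merge(fb, on=["x0", "y0", "x1", "y1"])
        assert merged.empty

    def test_invalid_roi_count_rejected(self):
        spec = CohortSpec(n_cores_per_group=(2, 2), rois_per_core=4)
        with pytest.raises(SpecValidationError, match="rois_per_core"):
            spec.validate()
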