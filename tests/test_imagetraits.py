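"""Morphometry correctness: segmentation against analytic shapes, the
furthest-point diameter against brute force, rind and bundle recovery
against rendered ground truth, and the Gaussian rim-ellipse closed forms."""

import math

import numpy as np
import pytest

from stalktraits import synthgen
from stalktraits.imagetraits import (
    CrossSectionImage,
    MorphometryConfig,
    RindMeasurementError,
    SegmentationError,
    bundle_area,
    detect_bundle_centers,
    ellipse_radii_from_eigenvalues,
    fit_bundle_gaussian,
    measure_section,
    rind_thickness,
    segment_stalk,
    stalk_diameter,
)
from conftest import match_bundles


def _disc_image(radius_cm=1.0, scale=0.005, pad_cm=0.3, fg=200.0, bg=10.0):
    n = int(2 * (radius_cm + pad_cm) / scale)
    xs = np.arange(n) * scale
    c = xs[n // 2]
    X, Y = np.meshgrid(xs, xs)
    img = np.where((X - c) ** 2 + (Y - c) ** 2 <= radius_cm**2, fg, bg)
    return CrossSectionImage(img, scale)


class TestSegmentStalk:
    def test_disc_area_matches_pi_r_squared(self):
        image = _disc_image(radius_cm=1.0)
        boundary = segment_stalk(image)
        assert boundary.area_cm2 == pytest.approx(math.pi, rel=0.02)

    def test_ellipse_area_matches_pi_ab(self, noiseless_image):
        spec, image, _ = noiseless_image
        a, b = spec.stalk_semi_axes_cm
        boundary = segment_stalk(image)
        assert boundary.area_cm2 == pytest.approx(math.pi * a * b, rel=0.02)

    def test_blank_image_raises(self):
        image = CrossSectionImage(np.full((50, 50), 7.0), 0.01)
        with pytest.raises(SegmentationError):
            segment_stalk(image)

    def test_border_touching_component_raises(self):
        arr = np.full((60, 60), 10.0)
        arr[:30, :] = 200.0  # bright block touching the top border
        with pytest.raises(SegmentationError, match="border"):
            segment_stalk(CrossSectionImage(arr, 0.01))


class TestStalkDiameter:
    def test_unit_square_corners(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert stalk_diameter(pts) == pytest.approx(math.sqrt(2))

    def test_rendered_circle_diameter(self):
        image = _disc_image(radius_cm=1.2)
        boundary = segment_stalk(image)
        assert stalk_diameter(boundary) == pytest.approx(
            2.4, abs=2 * image.scale_cm_per_px
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_pairwise_maximum(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(rng.integers(3, 400), 2))
        brute = math.sqrt(
            max(((p - q) ** 2).sum() for p in pts for q in pts)
        )
        assert stalk_diameter(pts) == pytest.approx(brute, rel=1e-12)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            stalk_diameter(np.array([[0.0, 0.0]]))


class TestRindThickness:
    def test_noiseless_ground_truth_recovery(self, noiseless_image):
        spec, image, truth = noiseless_image
        boundary = segment_stalk(image)
        est = rind_thickness(image, boundary)
        assert est == pytest.approx(truth.rind_thickness_cm, rel=0.10)

    def test_three_level_transition_is_exact_annulus_width(self):
        # circular stalk: along every radial ray the annulus width equals
        # the nominal rind thickness, so recovery should be ~1 px accurate
        spec = synthgen.ImageSpec(
            stalk_semi_axes_cm=(1.0, 1.0), rind_thickness_cm=0.25,
            bundle_count=0, noise_sd=0.0, seed=0,
        )
        image, _ = synthgen.render_section_image(spec)
        boundary = segment_stalk(image)
        est = rind_thickness(image, boundary)
        assert est == pytest.approx(0.25, abs=2 * image.scale_cm_per_px)

    def test_uniform_disc_without_annulus_raises(self):
        image = _disc_image(fg=150.0, bg=10.0)
        boundary = segment_stalk(image)
        with pytest.raises(RindMeasurementError):
            rind_thickness(image, boundary)


class TestDetectBundleCenters:
    def test_zero_bundle_image_gives_empty_list(self, ):
        spec = synthgen.ImageSpec(bundle_count=0, seed=1)
        image, _ = synthgen.render_section_image(spec)
        boundary = segment_stalk(image)
        assert detect_bundle_centers(image, boundary) == []

    def test_high_snr_recall_and_precision(self, default_image):
        spec, image, truth = default_image
        boundary = segment_stalk(image)
        centers = np.array(detect_bundle_centers(image, boundary))
        true_centers = truth.bundle_centers()
        d = np.sqrt(
            ((centers[:, None, :] - true_centers[None, :, :]) ** 2).sum(-1)
        )
        # every truth matched and no spurious detections
        assert (d.min(axis=0) <= 0.05).mean() >= 0.95
        assert (d.min(axis=1) <= 0.05).mean() >= 0.95

    def test_close_pair_keeps_only_more_prominent(self):
        scale = 0.005
        n = 200
        xs = np.arange(n) * scale
        X, Y = np.meshgrid(xs, xs)
        c = xs[n // 2]
        img = np.full((n, n), 10.0)
        stalk = (X - c) ** 2 + (Y - c) ** 2 <= 0.45**2
        img[stalk] = 80.0
        rind = ((X - c) ** 2 + (Y - c) ** 2 <= 0.45**2) & (
            (X - c) ** 2 + (Y - c) ** 2 > 0.40**2
        )
        img[rind] = 220.0
        sig = 0.015
        for (bx, amp) in ((c - 0.02, 100.0), (c + 0.02, 60.0)):  # 0.04 cm apart
            img += amp * np.exp(-(((X - bx) ** 2) + (Y - c) ** 2) / (2 * sig**2))
        image = CrossSectionImage(np.clip(img, 0, 255), scale)
        boundary = segment_stalk(image)
        config = MorphometryConfig(min_bundle_spacing_cm=0.10)
        centers = detect_bundle_centers(image, boundary, config)
        assert len(centers) == 1
        assert centers[0][0] == pytest.approx(c - 0.02, abs=0.01)


class TestGaussianFit:
    def test_isotropic_blob_area_is_2_pi_sigma_sq_at_1_over_e_rim(self):
        scale, n, sig = 0.01, 101, 0.03
        xs = np.arange(n) * scale
        X, Y = np.meshgrid(xs, xs)
        c = xs[n // 2]
        z = 50.0 + 120.0 * np.exp(-((X - c) ** 2 + (Y - c) ** 2) / (2 * sig**2))
        image = CrossSectionImage(z, scale)
        config = MorphometryConfig(
            rim_fraction=1 / math.e, min_bundle_spacing_cm=0.5,
            fit_window_radius_factor=0.9,
        )
        fit = fit_bundle_gaussian(image, (c, c), config)
        assert fit.converged
        assert fit.area_cm2 == pytest.approx(2 * math.pi * sig**2, rel=1e-9)
        assert fit.radii_cm[0] == pytest.approx(sig * math.sqrt(2), rel=1e-9)

    def test_radii_and_area_closed_form(self):
        r1, r2, area = ellipse_radii_from_eigenvalues(4.0, 1.0, 0.5)
        assert r1 == pytest.approx(2 * math.sqrt(2 * math.log(2)), abs=1e-4)
        assert r2 == pytest.approx(1.1774, abs=1e-4)
        assert area == pytest.approx(8.7103, abs=1e-3)

    def test_rotated_noisy_blob_recovers_radii(self):
        rng = np.random.default_rng(42)
        scale, n = 1.0, 41  # pixel units: sigma_x=3 px, sigma_y=2 px
        xs = np.arange(n) * scale
        X, Y = np.meshgrid(xs, xs)
        c = xs[n // 2]
        phi = math.radians(30)
        R = np.array([[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]])
        cov = R @ np.diag([9.0, 4.0]) @ R.T
        inv = np.linalg.inv(cov)
        d = np.stack([X - c, Y - c], axis=-1)
        q = np.einsum("...i,ij,...j", d, inv, d)
        z = 30.0 + 120.0 * np.exp(-0.5 * q) + rng.normal(0, 2.0, (n, n))
        image = CrossSectionImage(z, scale)
        config = MorphometryConfig(
            min_bundle_spacing_cm=25.0, fit_window_radius_factor=0.8
        )
        fit = fit_bundle_gaussian(image, (c, c), config)
        k = math.sqrt(2 * math.log(2))
        assert fit.converged
        assert fit.radii_cm[0] == pytest.approx(3 * k, rel=0.05)
        assert fit.radii_cm[1] == pytest.approx(2 * k, rel=0.05)

    def test_amplitude_invariance_of_rim_radii(self):
        # rim defined as a fraction of peak: doubling A leaves (r1, r2) fixed
        scale, n, sig = 0.01, 81, 0.025
        xs = np.arange(n) * scale
        X, Y = np.meshgrid(xs, xs)
        c = xs[n // 2]
        config = MorphometryConfig(min_bundle_spacing_cm=0.45)
        areas = []
        for amp in (60.0, 120.0):
            z = 40.0 + amp * np.exp(-((X - c) ** 2 + (Y - c) ** 2) / (2 * sig**2))
            fit = fit_bundle_gaussian(CrossSectionImage(z, scale), (c, c), config)
            areas.append(fit.area_cm2)
        assert areas[0] == pytest.approx(areas[1], rel=1e-6)

    def test_rotation_invariance_of_area(self):
        scale, n = 1.0, 41
        xs = np.arange(n) * scale
        X, Y = np.meshgrid(xs, xs)
        c = xs[n // 2]
        config = MorphometryConfig(min_bundle_spacing_cm=25.0)
        areas = []
        for deg in (0, 30, 60, 90, 135):
            phi = math.radians(deg)
            R = np.array(
                [[math.cos(phi), -math.sin(phi)], [math.sin(phi), math.cos(phi)]]
            )
            inv = np.linalg.inv(R @ np.diag([9.0, 4.0]) @ R.T)
            d = np.stack([X - c, Y - c], axis=-1)
            q = np.einsum("...i,ij,...j", d, inv, d)
            z = 30.0 + 100.0 * np.exp(-0.5 * q)
            fit = fit_bundle_gaussian(CrossSectionImage(z, scale), (c, c), config)
            areas.append(fit.area_cm2)
        assert np.ptp(areas) / np.mean(areas) < 0.01

    def test_window_outside_image_raises(self):
        image = _disc_image()
        with pytest.raises(ValueError, match="window"):
            fit_bundle_gaussian(image, (0.0, 0.0))


class TestBundleArea:
    def test_unit_radii_give_pi(self):
        from stalktraits.imagetraits import BundleFit

        fit = BundleFit(
            center_cm=(0, 0), amplitude=10, baseline=0,
            covariance_cm2=np.eye(2), eigenvalues=(1, 1), radii_cm=(1.0, 1.0),
            area_cm2=math.pi, rim_fraction=0.5, converged=True,
        )
        assert bundle_area(fit) == pytest.approx(math.pi)

    def test_unconverged_fit_raises(self):
        from stalktraits.imagetraits import BundleFit

        fit = BundleFit(
            center_cm=(0, 0), amplitude=1, baseline=0,
            covariance_cm2=np.eye(2), eigenvalues=(1, 1), radii_cm=(1.0, 1.0),
            area_cm2=math.pi, rim_fraction=0.5, converged=False,
        )
        with pytest.raises(ValueError):
            bundle_area(fit)

    def test_degenerate_zero_radius_raises(self):
        from stalktraits.imagetraits import BundleFit

        fit = BundleFit(
            center_cm=(0, 0), amplitude=1, baseline=0,
            covariance_cm2=np.eye(2), eigenvalues=(1, 0), radii_cm=(1.0, 0.0),
            area_cm2=0.0, rim_fraction=0.5, converged=True,
        )
        with pytest.raises(ValueError):
            bundle_area(fit)


class TestMeasureSection:
    def test_full_chain_ground_truth_recovery(self, default_image):
        spec, image, truth = default_image
        traits, fits = measure_section(image)
        assert traits.diameter_cm == pytest.approx(truth.diameter_cm, rel=0.01)
        assert traits.bundle_density_per_cm2 == pytest.approx(
            truth.bundle_density_per_cm2, rel=0.10
        )
        recall, precision, area_errors = match_bundles(truth, fits)
        assert recall >= 0.95 and precision >= 0.95
        assert np.median(area_errors) <= 0.10
        assert traits.bundle_density_per_cm2 == pytest.approx(
            traits.bundle_count / traits.cross_section_area_cm2
        )

    def test_zero_bundle_image(self):
        spec = synthgen.ImageSpec(bundle_count=0, seed=2)
        image, _ = synthgen.render_section_image(spec)
        traits, fits = measure_section(image)
        assert traits.bundle_count == 0
        assert traits.bundle_density_per_cm2 == 0.0
        assert math.isnan(traits.mean_bundle_area_cm2)

    def test_error_propagation_names_stage(self):
        blank = CrossSectionImage(np.full((64, 64), 3.0), 0.01)
        with pytest.raises(RuntimeError, match="segmentation"):
            measure_section(blank)


def test_resolution_refinement_shrinks_errors():
    """Halving the pixel size (at fixed physical geometry) at least halves
    the absolute error of area, diameter and rind thickness on a noiseless
    image (up to a one-fine-pixel floor for the boundary-driven measures)."""
    errs = {}
    for scale, npx in ((0.01, 256), (0.005, 512)):
        spec = synthgen.ImageSpec(
            height_px=npx, width_px=npx, scale_cm_per_px=scale,
            bundle_count=0, noise_sd=0.0, seed=0,
        )
        image, truth = synthgen.render_section_image(spec)
        boundary = segment_stalk(image)
        a, b = spec.stalk_semi_axes_cm
        errs[scale] = (
            abs(boundary.area_cm2 - math.pi * a * b),
            abs(stalk_diameter(boundary) - truth.diameter_cm),
            abs(rind_thickness(image, boundary) - truth.rind_thickness_cm),
        )
    fine_px = 0.005
    for coarse, fine in zip(errs[0.01], errs[0.005]):
        assert fine <= max(0.5 * coarse, fine_px)
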