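"""Shape/intensity statistics: FWHM axes, size fit, PC, polygon ROI."""

import numpy as np
import pytest

from granulekit import (
    ImageStack,
    aspect_ratio,
    fit_size_distribution,
    integrated_density,
    label_objects,
    measure_objects,
    partition_coefficient,
    threshold_image,
    volume_intensity_relation,
)
from granulekit.segmentation import GranuleRecord
from granulekit.synthetic import GranuleFieldParams, generate_granule_image


def _single_granule(axis_ratio=1.0, diameter=400.0, voxel=40.0, seed=0):
    params = GranuleFieldParams(
        field_shape=(48, 48, 48),
        voxel_size_nm=(voxel,) * 3,
        n_granules=1,
        diameter_mean_nm=diameter,
        diameter_sd_nm=0.0,
        axis_ratio=axis_ratio,
        seed=seed,
    )
    stack, truth = generate_granule_image(params)
    labels = label_objects(threshold_image(stack, method="fraction_of_max", fraction=0.5))
    (rec,) = measure_objects(labels, stack)
    return stack, rec, truth


class TestAspectRatio:
    def test_sphere_ratio_unity(self):
        stack, rec, _ = _single_granule()
        _, _, ratio = aspect_ratio(stack, rec)
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_two_to_one_ellipsoid(self):
        stack, rec, _ = _single_granule(axis_ratio=2.0)
        major, minor, ratio = aspect_ratio(stack, rec)
        assert ratio == pytest.approx(2.0, rel=0.10)
        assert major == pytest.approx(800.0, rel=0.10)
        assert minor == pytest.approx(400.0, rel=0.10)

    def test_intensity_scale_invariance(self):
        stack, rec, _ = _single_granule(axis_ratio=1.5)
        _, _, r1 = aspect_ratio(stack, rec)
        scaled = ImageStack(stack.data * 37.0, stack.channels, stack.voxel_size_nm)
        _, _, r2 = aspect_ratio(scaled, rec)
        assert r2 == pytest.approx(r1, rel=1e-9)

    def test_rotation_90deg_invariance(self):
        """Rotating the grid by 90° changes the ratio by < 2%."""
        stack, rec, _ = _single_granule(axis_ratio=2.0)
        _, _, r1 = aspect_ratio(stack, rec)
        rot = ImageStack(
            np.rot90(stack.data, axes=(2, 3)).copy(), stack.channels, stack.voxel_size_nm
        )
        labels = label_objects(threshold_image(rot, method="fraction_of_max", fraction=0.5))
        (rec2,) = measure_objects(labels, rot)
        _, _, r2 = aspect_ratio(rot, rec2)
        assert r2 == pytest.approx(r1, rel=0.02)

    def test_degenerate_object_rejected(self):
        img = np.zeros((6, 6, 6))
        img[3, 3, 3] = 10.0
        st = ImageStack(img[np.newaxis], ["c"], (50.0,) * 3)
        (rec,) = measure_objects(label_objects(img > 0), st)
        with pytest.raises(ValueError):
            aspect_ratio(st, rec)


class TestSizeDistribution:
    def test_constant_population(self):
        fit = fit_size_distribution([400.0, 400.0, 400.0])
        assert fit.mean_diameter_nm == 400.0
        assert fit.sd_diameter_nm == 0.0

    def test_recovers_generating_gaussian_within_clt_band(self):
        rng = np.random.default_rng(1)
        d = rng.normal(400.0, 129.0, size=10_000)
        fit = fit_size_distribution(d)
        assert abs(fit.mean_diameter_nm - 400.0) <= 3 * 129.0 / np.sqrt(10_000)
        assert fit.sd_diameter_nm == pytest.approx(129.0, rel=0.05)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(2)
        d = rng.normal(400.0, 50.0, size=100)
        a = fit_size_distribution(d)
        b = fit_size_distribution(d + 37.0)
        assert b.mean_diameter_nm == pytest.approx(a.mean_diameter_nm + 37.0)
        assert b.sd_diameter_nm == pytest.approx(a.sd_diameter_nm)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_size_distribution([400.0])


def _fake_records(volumes, intensities):
    return [
        GranuleRecord(
            id=i,
            centroid_nm=(0.0, 0.0),
            volume=float(v),
            equivalent_diameter_nm=1.0,
            major_axis_nm=1.0,
            minor_axis_nm=1.0,
            aspect_ratio=1.0,
            n_voxels=1,
            mean_intensity={"c": float(x)},
            integrated_intensity={"c": float(x)},
        )
        for i, (v, x) in enumerate(zip(volumes, intensities))
    ]


class TestVolumeIntensityRelation:
    def test_proportional_intensity_gives_zero_slope(self):
        vols = np.linspace(0.01, 0.1, 20)
        rel = volume_intensity_relation(_fake_records(vols, 500.0 * vols), "c")
        assert rel.slope == pytest.approx(0.0, abs=1e-9)

    def test_quadratic_intensity_gives_positive_slope(self):
        vols = np.linspace(0.01, 0.1, 20)
        rel = volume_intensity_relation(_fake_records(vols, vols**2), "c")
        assert rel.slope > 3 * rel.slope_se

    def test_constant_concentration_with_noise_within_2se(self):
        rng = np.random.default_rng(3)
        vols = rng.uniform(0.02, 0.2, size=200)
        copies = rng.poisson(500.0 * vols)
        rel = volume_intensity_relation(_fake_records(vols, copies.astype(float)), "c")
        assert abs(rel.slope) <= 2 * rel.slope_se

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            volume_intensity_relation(_fake_records([0.1, 0.2], [1, 2]), "c")


class TestPartitionCoefficient:
    def test_two_level_exact(self, two_level_image):
        stack, mask = two_level_image
        pc = partition_coefficient(stack, "c", mask, exclusion_halo_voxels=0)
        assert pc.value == pytest.approx(10.0)

    def test_uniform_image_unity(self):
        st = ImageStack(np.full((1, 30, 30), 7.0), ["c"], (50.0, 50.0))
        mask = np.zeros((30, 30), bool)
        mask[10:20, 10:20] = True
        assert partition_coefficient(st, "c", mask).value == pytest.approx(1.0)

    def test_global_scaling_invariance(self, two_level_image):
        stack, mask = two_level_image
        a = partition_coefficient(stack, "c", mask).value
        scaled = ImageStack(stack.data * 3.7, stack.channels, stack.voxel_size_nm)
        assert partition_coefficient(scaled, "c", mask).value == pytest.approx(a)

    def test_noisy_two_level_within_2pct(self):
        rng = np.random.default_rng(5)
        img = np.full((400, 400), 100.0)
        mask = np.zeros((400, 400), bool)
        mask[100:300, 100:300] = True
        img[mask] = 1000.0
        img += rng.normal(0, 50.0, img.shape)
        st = ImageStack(img[np.newaxis], ["c"], (50.0, 50.0))
        pc = partition_coefficient(st, "c", mask, exclusion_halo_voxels=1)
        assert pc.value == pytest.approx(10.0, rel=0.02)

    def test_all_true_mask_rejected(self):
        st = ImageStack(np.ones((1, 10, 10)), ["c"], (50.0, 50.0))
        with pytest.raises(ValueError):
            partition_coefficient(st, "c", np.ones((10, 10), bool))


class TestIntegratedDensity:
    def test_square_covering_100_centers(self):
        st = ImageStack(np.ones((1, 20, 20)), ["c"], (10.0, 10.0))
        # voxel centers at 5, 15, ..., 195 nm; cover centers 0..9 both axes
        poly = np.array([[0.0, 0.0], [0.0, 100.0], [100.0, 100.0], [100.0, 0.0]])
        assert integrated_density(st, "c", poly) == pytest.approx(100.0)

    def test_linearity_in_intensity(self):
        rng = np.random.default_rng(6)
        img = rng.uniform(size=(25, 25))
        poly = np.array([[30.0, 20.0], [200.0, 50.0], [180.0, 230.0], [40.0, 210.0]])
        a = integrated_density(ImageStack(img[None], ["c"], (10.0, 10.0)), "c", poly)
        b = integrated_density(ImageStack(2 * img[None], ["c"], (10.0, 10.0)), "c", poly)
        assert b == pytest.approx(2 * a)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_point_in_polygon(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(size=(30, 30))
        st = ImageStack(img[None], ["c"], (10.0, 10.0))
        k = rng.integers(3, 8)
        poly = rng.uniform(5, 295, size=(k, 2))

        def inside_scalar(py, px):
            # independent even-odd ray cast, one point at a time
            c = False
            for i in range(k):
                y1, x1 = poly[i]
                y2, x2 = poly[(i + 1) % k]
                if (y1 > py) != (y2 > py):
                    xc = (x2 - x1) * (py - y1) / (y2 - y1) + x1
                    if px < xc:
                        c = not c
            return c

        expected = sum(
            img[iy, ix]
            for iy in range(30)
            for ix in range(30)
            if inside_scalar((iy + 0.5) * 10.0, (ix + 0.5) * 10.0)
        )
        assert integrated_density(st, "c", poly) == pytest.approx(expected)

    def test_degenerate_polygon_rejected(self):
        st = ImageStack(np.ones((1, 5, 5)), ["c"], (10.0, 10.0))
        with pytest.raises(ValueError):
            integrated_density(st, "c", np.array([[0.0, 0.0], [10.0, 10.0]]))

    def test_vertices_outside_field_rejected(self):
        st = ImageStack(np.ones((1, 5, 5)), ["c"], (10.0, 10.0))
        poly = np.array([[0.0, 0.0], [0.0, 100.0], [100.0, 0.0]])
        with pytest.raises(ValueError):
            integrated_density(st, "c", poly)
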