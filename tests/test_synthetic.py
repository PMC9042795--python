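"""Generator contracts: determinism, conservation, exact ground truth."""

import math

import numpy as np
import pytest

from granulekit import label_objects, threshold_image
from granulekit.segmentation import measure_objects
from granulekit.synthetic import (
    FieldTooCrowdedError,
    FrapSimParams,
    GranuleFieldParams,
    GroundTruth,
    generate_calibration_ladder,
    generate_frap_trace,
    generate_granule_image,
    generate_intensity_population,
    generate_polarity_field,
    generate_two_channel_field,
)


def small_params(**kw):
    base = dict(
        field_shape=(20, 80, 80),
        voxel_size_nm=(100.0, 50.0, 50.0),
        n_granules=5,
        diameter_mean_nm=400.0,
        diameter_sd_nm=50.0,
        min_separation_nm=1200.0,
        seed=1,
    )
    base.update(kw)
    return GranuleFieldParams(**base)


class TestGranuleImage:
    def test_identical_seed_bit_identical(self):
        a_img, a_truth = generate_granule_image(small_params())
        b_img, b_truth = generate_granule_image(small_params())
        assert np.array_equal(a_img.data, b_img.data)
        assert a_truth.to_json() == b_truth.to_json()

    def test_different_seed_differs(self):
        a_img, _ = generate_granule_image(small_params())
        b_img, _ = generate_granule_image(small_params(seed=2))
        assert not np.array_equal(a_img.data, b_img.data)

    def test_empty_field(self):
        img, truth = generate_granule_image(small_params(n_granules=0, background_level=5.0))
        assert truth.granules == []
        assert np.all(img.data == 5.0)

    def test_photon_conservation_total(self):
        copies = {1: 0.5, 2: 0.3, 3: 0.2}
        img, truth = generate_granule_image(
            small_params(copies_distribution=copies, unit_intensity=1000.0)
        )
        expected = sum(g.copies for g in truth.granules) * 1000.0
        assert img.data.sum() == pytest.approx(expected, rel=1e-9)

    def test_photon_conservation_per_granule(self):
        """Integrated above-background signal per granule = copies x unit."""
        img, truth = generate_granule_image(
            small_params(copies_distribution={1: 0.6, 2: 0.4})
        )
        mask = threshold_image(img, method="fixed", value=1e-9)
        labels = label_objects(mask)
        records = measure_objects(labels, img)
        assert len(records) == len(truth.granules)
        # match objects to truth by centroid
        t_centroids = truth.centroids_nm()
        for r in records:
            i = int(np.argmin(np.linalg.norm(t_centroids - np.array(r.centroid_nm), axis=1)))
            expected = truth.granules[i].copies * 1000.0
            assert r.integrated_intensity["granules"] == pytest.approx(expected, rel=0.01)

    def test_diameters_truncated_above_two_voxels(self):
        _, truth = generate_granule_image(
            small_params(diameter_mean_nm=220.0, diameter_sd_nm=120.0, n_granules=30,
                         min_separation_nm=0.0)
        )
        assert all(g.diameter_nm > 2 * 100.0 for g in truth.granules)

    def test_crowded_field_raises(self):
        with pytest.raises(FieldTooCrowdedError):
            generate_granule_image(small_params(n_granules=200, min_separation_nm=2000.0))

    def test_ground_truth_round_trip(self, tmp_path):
        _, truth = generate_granule_image(small_params())
        p = tmp_path / "truth.json"
        truth.save(p)
        assert GroundTruth.load(p) == truth

    def test_poisson_noise_changes_image_deterministically(self):
        a, _ = generate_granule_image(small_params(noise_model="poisson", background_level=10))
        b, _ = generate_granule_image(small_params(noise_model="poisson", background_level=10))
        assert np.array_equal(a.data, b.data)
        assert np.all(a.data == np.round(a.data))


class TestTwoChannel:
    def test_partner_count_exact(self):
        p = small_params(field_shape=(120, 120), voxel_size_nm=(50.0, 50.0),
                         min_separation_nm=500.0)
        for f, n_ref in [(0.5, 20), (0.3, 21), (1.0, 10)]:
            _, _, truth = generate_two_channel_field(p, n_ref, 25, f, jitter_sd_nm=0)
            partnered = [g for g in truth.granules if g.partner_id is not None]
            assert len(partnered) == round(f * n_ref)

    def test_full_coloc_zero_jitter_distance_zero(self):
        p = small_params(field_shape=(150, 150), voxel_size_nm=(50.0, 50.0),
                         min_separation_nm=600.0)
        _, _, truth = generate_two_channel_field(p, 10, 10, 1.0, jitter_sd_nm=0)
        ref = truth.centroids_nm("ref")
        tgt = truth.centroids_nm("target")
        for g in truth.granules:
            if g.partner_id is not None:
                d = np.linalg.norm(np.array(g.centroid_nm) - ref[g.partner_id])
                assert d == pytest.approx(0.0, abs=1e-9)
        assert len(tgt) == 10

    def test_zero_fraction_no_partners(self):
        p = small_params(field_shape=(150, 150), voxel_size_nm=(50.0, 50.0),
                         min_separation_nm=500.0)
        _, _, truth = generate_two_channel_field(p, 15, 15, 0.0)
        assert all(g.partner_id is None for g in truth.granules)


class TestFrapTrace:
    def test_closed_form_value(self):
        trace, _ = generate_frap_trace(
            FrapSimParams(I0=0.2, I1=0.5, tau_s=10.0, frame_interval_s=1.0,
                          n_postbleach=30)
        )
        t_rel = trace.time_s - trace.t_bleach
        i = int(np.argmin(np.abs(t_rel - 10.0)))
        assert trace.roi[i] == pytest.approx(0.2 + 0.5 * (1 - math.exp(-1)), abs=1e-12)

    def test_full_recovery_limit(self):
        trace, _ = generate_frap_trace(
            FrapSimParams(I0=0.0, I1=1.0, tau_s=1.0, n_postbleach=100, frame_interval_s=1.0)
        )
        assert trace.roi[-1] == pytest.approx(1.0, abs=1e-6)

    def test_prebleach_equals_reference(self):
        trace, _ = generate_frap_trace(FrapSimParams(acquisition_bleach_rate=0.01))
        pre = slice(0, trace.bleach_index)
        assert np.allclose(trace.roi[pre], trace.reference[pre])

    def test_true_fit_reports_derived_quantities(self):
        _, fit = generate_frap_trace(FrapSimParams(I0=0.2, I1=0.5, tau_s=10.0))
        assert fit.immobile_fraction == pytest.approx(0.375)
        assert fit.t_half_s == pytest.approx(10 * math.log(2))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            FrapSimParams(I0=0.7, I1=0.5)
        with pytest.raises(ValueError):
            FrapSimParams(tau_s=0)
        with pytest.raises(ValueError):
            FrapSimParams(n_prebleach=0)


class TestPopulationAndLadder:
    def test_single_copy_no_noise(self):
        x, copies = generate_intensity_population(1000.0, {1: 1.0}, 50, 0.0, seed=0)
        assert np.all(x == 1000.0)
        assert np.all(copies == 1)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            generate_intensity_population(1000.0, {1: 1.0}, 0)

    def test_copy_mix_frequencies(self):
        _, copies = generate_intensity_population(1000.0, {1: 0.7, 2: 0.3}, 5000, 0.1, seed=5)
        frac2 = np.mean(copies == 2)
        assert frac2 == pytest.approx(0.3, abs=3 * math.sqrt(0.3 * 0.7 / 5000))

    def test_ladder_noise_free_means(self):
        frames = generate_calibration_ladder([1e-6, 2e-6], 1e9, noise_sd=0.0)
        assert frames[0][1].mean() == pytest.approx(1000.0)
        assert frames[1][1].mean() == pytest.approx(2000.0)

    def test_ladder_single_concentration_rejected(self):
        with pytest.raises(ValueError):
            generate_calibration_ladder([1e-6, 1e-6], 1e9)


class TestPolarityField:
    def test_symmetric_weight_near_zero(self):
        _, _, true_disp = generate_polarity_field((50, 80), 1, 0.5, 5000, seed=3)
        assert abs(true_disp) < 0.02

    def test_biased_weight_expectation(self):
        # E[u] = w * 0.25 + (1 - w) * (-0.25)
        _, _, true_disp = generate_polarity_field((50, 80), 1, 0.7, 5000, seed=4)
        assert true_disp == pytest.approx(0.1, abs=0.02)

    def test_invalid_weight(self):
        with pytest.raises(ValueError):
            generate_polarity_field((20, 20), 0, 1.5, 10)
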