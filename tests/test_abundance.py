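"""Copy-number and concentration calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from granulekit import (
    MixtureModel,
    copy_number,
    fit_calibration_curve,
    fit_gaussian_mixture,
    molar_concentration,
    protein_concentration,
    unit_intensity,
)
from granulekit.abundance import AVOGADRO
from granulekit.synthetic import generate_calibration_ladder, generate_intensity_population


@pytest.fixture(scope="module")
def two_copy_population():
    return generate_intensity_population(1000.0, {1: 0.7, 2: 0.3}, 5000, 0.1, seed=5)


class TestMixture:
    def test_single_component_matches_sample_moments(self):
        rng = np.random.default_rng(0)
        x = rng.normal(500.0, 20.0, size=400)
        m = fit_gaussian_mixture(x, K=1)
        assert m.means[0] == pytest.approx(x.mean())
        assert m.sds[0] == pytest.approx(x.std(), rel=1e-6)
        assert m.weights[0] == 1.0

    def test_two_copy_recovery(self, two_copy_population):
        x, _ = two_copy_population
        m = fit_gaussian_mixture(x, K=2, seed=5)
        assert m.means[0] == pytest.approx(1000.0, rel=0.02)
        assert m.means[1] == pytest.approx(2000.0, rel=0.02)
        assert m.weights[0] == pytest.approx(0.7, abs=0.05)
        assert m.weights[1] == pytest.approx(0.3, abs=0.05)

    def test_bic_selects_two_components(self, two_copy_population):
        x, _ = two_copy_population
        m = fit_gaussian_mixture(x, K_range=(1, 4), seed=5)
        assert m.K == 2

    def test_matches_sklearn_reference(self, two_copy_population):
        """Independent EM implementation (scikit-learn) agrees on the modes."""
        sklearn_mixture = pytest.importorskip("sklearn.mixture")
        x, _ = two_copy_population
        ours = fit_gaussian_mixture(x, K=2, seed=5)
        gm = sklearn_mixture.GaussianMixture(2, random_state=0, n_init=3).fit(
            x.reshape(-1, 1)
        )
        ref_means = np.sort(gm.means_.ravel())
        assert np.allclose(ours.means, ref_means, rtol=0.01)

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_mixture(np.arange(15.0), K=2)

    def test_invalid_model_parameters_rejected(self):
        with pytest.raises(ValueError):
            MixtureModel(means=[1.0], sds=[0.0], weights=[1.0])
        with pytest.raises(ValueError):
            MixtureModel(means=[1.0, 2.0], sds=[1.0, 1.0], weights=[0.6, 0.6])


class TestUnitIntensity:
    def test_largest_weight_wins(self):
        m = MixtureModel(means=[1000.0, 2000.0], sds=[50.0, 50.0], weights=[0.7, 0.3])
        assert unit_intensity(m) == 1000.0

    def test_tie_breaks_to_smaller_mean(self):
        m = MixtureModel(means=[2000.0, 1000.0], sds=[50.0, 50.0], weights=[0.5, 0.5])
        assert unit_intensity(m) == 1000.0

    def test_fitted_unit_within_2pct(self, two_copy_population):
        x, _ = two_copy_population
        unit = unit_intensity(fit_gaussian_mixture(x, K=2, seed=5))
        assert unit == pytest.approx(1000.0, rel=0.02)

    def test_scale_equivariance(self, two_copy_population):
        x, _ = two_copy_population
        u1 = unit_intensity(fit_gaussian_mixture(x, K=2, seed=5))
        u2 = unit_intensity(fit_gaussian_mixture(x * 3.0, K=2, seed=5))
        assert u2 == pytest.approx(3.0 * u1, rel=1e-6)
        raw1, _ = copy_number(x, u1)
        raw2, _ = copy_number(x * 3.0, u2)
        assert np.allclose(raw1, raw2, rtol=1e-9)


class TestCopyNumber:
    def test_simple_division(self):
        assert copy_number(3000.0, 1000.0) == (3.0, 3)
        assert copy_number(0.0, 1000.0) == (0.0, 0)

    def test_invalid_unit(self):
        with pytest.raises(ValueError):
            copy_number(1000.0, 0.0)

    def test_total_copies_conservation(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(100, 5000, size=200)
        raw, _ = copy_number(x, 700.0)
        assert raw.sum() == pytest.approx(x.sum() / 700.0, rel=1e-12)

    def test_rounded_copies_accuracy_at_high_snr(self):
        """Known 1–8 copy granules with shot noise: >= 95% called exactly."""
        rng = np.random.default_rng(2)
        unit = 1000.0  # SNR = sqrt(1000) ~ 32 per copy
        true = rng.integers(1, 9, size=2000)
        intensity = rng.poisson(true * unit).astype(float)
        _, called = copy_number(intensity, unit)
        assert np.mean(called == true) >= 0.95


class TestMolarConcentration:
    def test_one_copy_per_femtoliter(self):
        assert molar_concentration(1, 1e-15) == pytest.approx(1.6606e-9, rel=1e-4)

    def test_42_copies_in_400nm_sphere(self):
        v_liters = (4.0 / 3.0) * np.pi * (200e-9) ** 3 * 1e3  # m^3 -> L
        assert v_liters == pytest.approx(3.351e-17, rel=1e-3)
        assert molar_concentration(42, v_liters) == pytest.approx(2.081e-6, rel=1e-3)

    def test_zero_copies(self):
        assert molar_concentration(0, 1e-15) == 0.0

    def test_invalid_volume(self):
        with pytest.raises(ValueError):
            molar_concentration(1, 0.0)

    @given(
        copies=st.integers(0, 10_000),
        vol=st.floats(1e-20, 1e-12),
    )
    @settings(max_examples=200, deadline=None)
    def test_closed_form_on_random_pairs(self, copies, vol):
        assert molar_concentration(copies, vol) == copies / (AVOGADRO * vol)


class TestCalibrationCurve:
    def test_exact_line_recovered(self):
        c = np.array([1e-6, 2e-6, 5e-6, 10e-6])
        y = 2e9 * c + 37.0
        curve = fit_calibration_curve(c, y)
        assert curve.slope == pytest.approx(2e9)
        assert curve.intercept == pytest.approx(37.0)
        assert curve.r_squared == pytest.approx(1.0)

    def test_simulated_ladder_slope_within_3pct(self):
        ladder = generate_calibration_ladder(
            [1e-6, 2e-6, 4e-6, 6e-6, 8e-6, 10e-6], 1e9, noise_sd=200.0, seed=2
        )
        c = np.array([p[0] for p in ladder])
        y = np.array([p[1].mean() for p in ladder])
        curve = fit_calibration_curve(c, y)
        assert curve.slope == pytest.approx(1e9, rel=0.03)

    def test_identical_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration_curve([1e-6, 1e-6], [10.0, 12.0])


class TestProteinConcentration:
    def test_intercept_maps_to_zero(self):
        curve = fit_calibration_curve([1e-6, 2e-6], [1000.0, 2000.0])
        with pytest.warns(UserWarning, match="extrapolat"):
            assert protein_concentration(curve.intercept, curve) == pytest.approx(0.0)

    def test_round_trip(self):
        curve = fit_calibration_curve(
            np.array([1e-6, 2e-6, 5e-6]), np.array([1100.0, 2100.0, 5100.0])
        )
        c = 3e-6
        intensity = curve.slope * c + curve.intercept
        assert protein_concentration(intensity, curve) == pytest.approx(c)

    def test_simulated_granules_at_5uM(self):
        ladder = generate_calibration_ladder(
            [2e-6, 4e-6, 6e-6, 8e-6, 10e-6], 1e9, noise_sd=100.0, seed=7
        )
        curve = fit_calibration_curve(
            [p[0] for p in ladder], [p[1].mean() for p in ladder]
        )
        rng = np.random.default_rng(8)
        granule_means = 1e9 * 5e-6 + rng.normal(0, 100.0, size=50)
        rec = protein_concentration(granule_means, curve)
        assert np.median(rec) == pytest.approx(5e-6, rel=0.05)

    def test_negative_slope_rejected(self):
        curve = fit_calibration_curve([1e-6, 2e-6], [2000.0, 1000.0])
        with pytest.raises(ValueError):
            protein_concentration(1500.0, curve)
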