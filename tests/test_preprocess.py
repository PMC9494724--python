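"""Baseline removal, smoothing, thresholding, peak extraction, feature packing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ramantissue as rt
from ramantissue.errors import DegenerateSpectrumError
from ramantissue.preprocess import (
    PeakList,
    PreprocessConfig,
    als_smooth_batch,
    modpoly_baseline_batch,
)


def _poly(wn, coeffs):
    u = (wn - wn[0]) / (wn[-1] - wn[0])
    return np.polynomial.polynomial.polyval(u, coeffs)


def _gauss(wn, center, fwhm, amp):
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    return amp * np.exp(-0.5 * ((wn - center) / sigma) ** 2)


WN = np.arange(400.0, 1801.0, 1.0)


class TestBaseline:
    def test_pure_polynomial_is_fixed_point(self):
        s = rt.Spectrum(WN, _poly(WN, [1.0, 0.5, -0.2, 0.1, 0.3]))
        base = rt.fit_polynomial_baseline(s, order=4)
        np.testing.assert_allclose(base.intensities, s.intensities,
                                   rtol=1e-6, atol=1e-9)

    def test_constant_spectrum(self):
        s = rt.Spectrum(WN, np.full(len(WN), 2.5))
        base = rt.fit_polynomial_baseline(s)
        np.testing.assert_allclose(base.intensities, 2.5, rtol=1e-9)

    def test_recovers_polynomial_under_narrow_peak(self):
        true = _poly(WN, [0.8, 0.4, 0.3, -0.2, 0.1])
        s = rt.Spectrum(WN, true + _gauss(WN, 1002.0, 8.0, 1.0))
        base = rt.fit_polynomial_baseline(s, order=4)
        far = np.abs(WN - 1002.0) >= 24.0  # ≥ 3 widths from the peak
        rel = np.abs(base.intensities[far] - true[far]) / np.abs(true[far])
        assert rel.max() < 0.02

    def test_too_short_spectrum_rejected(self):
        with pytest.raises(ValueError):
            modpoly_baseline_batch(np.arange(4.0), np.ones(4), order=4)

    def test_subtract_then_add_back(self):
        rng = np.random.default_rng(0)
        s = rt.Spectrum(WN, rng.random(len(WN)))
        base = rt.fit_polynomial_baseline(s)
        diff = rt.subtract_baseline(s, base)
        assert diff.meta.baseline_corrected
        np.testing.assert_allclose(diff.intensities + base.intensities,
                                   s.intensities, atol=1e-12)
        zero = rt.subtract_baseline(s, s)
        np.testing.assert_allclose(zero.intensities, 0.0, atol=1e-15)

    def test_peak_amplitude_preserved_after_subtraction(self):
        true_base = _poly(WN, [0.5, 0.9, 0.4, -0.3, 0.2])
        s = rt.Spectrum(WN, true_base + _gauss(WN, 1313.0, 8.0, 0.8))
        base = rt.fit_polynomial_baseline(s)
        corrected = rt.subtract_baseline(s, base)
        apex = corrected.intensities[np.argmin(np.abs(WN - 1313.0))]
        assert apex == pytest.approx(0.8, rel=0.02)


class TestNormalize:
    @pytest.mark.parametrize("raw, expected", [
        ([0.0, 2.0, 4.0], [0.0, 0.5, 1.0]),
        ([-1.0, 0.0, 2.0], [-0.5, 0.0, 1.0]),
    ])
    def test_examples(self, raw, expected):
        s = rt.Spectrum([400.0, 401.0, 402.0], raw)
        out = rt.normalize_max(s)
        np.testing.assert_allclose(out.intensities, expected)
        assert out.meta.normalized

    def test_all_zero_is_degenerate(self):
        with pytest.raises(DegenerateSpectrumError):
            rt.normalize_max(rt.Spectrum([400.0, 401.0], [0.0, 0.0]))

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_scale_invariant_and_idempotent(self, c):
        rng = np.random.default_rng(4)
        s = rt.Spectrum(WN[:50], rng.random(50))
        one = rt.normalize_max(s)
        two = rt.normalize_max(s.with_intensities(c * s.intensities))
        np.testing.assert_allclose(one.intensities, two.intensities, rtol=1e-12)
        np.testing.assert_allclose(rt.normalize_max(one).intensities,
                                   one.intensities, rtol=1e-12)


class TestSmoothing:
    def test_constant_preserved(self):
        s = rt.Spectrum(WN, np.full(len(WN), 0.7))
        out = rt.als_smooth(s)
        np.testing.assert_allclose(out.intensities, 0.7, atol=1e-9)

    def test_noise_rmse_reduced(self):
        rng = np.random.default_rng(21)
        truth = _gauss(WN, 900.0, 40.0, 1.0) + 0.3
        noisy = truth + 0.05 * rng.standard_normal(len(WN))
        out = als_smooth_batch(noisy, lam=100.0, p=0.5)[0]
        assert np.sqrt(np.mean((out - truth) ** 2)) < np.sqrt(np.mean((noisy - truth) ** 2))

    def test_apex_shift_at_most_one_step(self):
        s = rt.Spectrum(WN, _gauss(WN, 1002.0, 8.0, 1.0))
        out = rt.als_smooth(s)
        assert abs(np.argmax(out.intensities) - np.argmax(s.intensities)) <= 1

    def test_invalid_parameters(self):
        s = rt.Spectrum(WN[:10], np.ones(10))
        with pytest.raises(ValueError):
            rt.als_smooth(s, lam=-1.0)
        with pytest.raises(ValueError):
            rt.als_smooth(s, p=1.5)

    def test_asymmetric_weights_track_lower_envelope(self):
        # small p biases the curve below the peaks (the classic ALS behaviour)
        s = _gauss(WN, 1002.0, 8.0, 1.0) + 0.2
        low = als_smooth_batch(s, lam=1e5, p=0.01, n_iter=10)[0]
        sym = als_smooth_batch(s, lam=1e5, p=0.5, n_iter=10)[0]
        apex = np.argmin(np.abs(WN - 1002.0))
        assert low[apex] < sym[apex]


class TestThreshold:
    def test_example_sequence(self):
        s = rt.Spectrum(np.arange(5, dtype=float) + 400,
                        [0.1, 0.5, 0.2, 0.9, 1.0])
        out = rt.threshold_filter(s, tau=0.3)
        np.testing.assert_allclose(out.intensities, [0, 0.5, 0, 0.9, 1.0])

    def test_only_max_survives(self):
        s = rt.Spectrum(np.arange(4, dtype=float) + 400, [0.1, 0.2, 1.0, 0.25])
        out = rt.threshold_filter(s, tau=0.3)
        np.testing.assert_allclose(out.intensities, [0, 0, 1.0, 0])

    def test_tau_zero_is_identity(self):
        rng = np.random.default_rng(5)
        vals = rng.random(20)
        vals[3] = 1.0
        s = rt.Spectrum(400.0 + np.arange(20.0), vals)
        np.testing.assert_allclose(rt.threshold_filter(s, 0.0).intensities, vals)

    def test_requires_normalised_input(self):
        s = rt.Spectrum([400.0, 401.0], [0.1, 0.5])
        with pytest.raises(ValueError):
            rt.threshold_filter(s)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_idempotent_never_increases_preserves_max(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random(30)
        vals[rng.integers(30)] = 1.0
        s = rt.Spectrum(400.0 + np.arange(30.0), vals)
        once = rt.threshold_filter(s)
        twice = rt.threshold_filter(once)
        np.testing.assert_array_equal(once.intensities, twice.intensities)
        assert np.all(once.intensities <= vals)
        assert once.intensities.max() == vals.max()


class TestPeaks:
    def test_single_gaussian_single_peak(self):
        s = rt.Spectrum(WN, _gauss(WN, 1002.0, 8.0, 1.0))
        s = rt.threshold_filter(rt.normalize_max(s))
        peaks = rt.extract_peaks(s)
        assert len(peaks) == 1
        assert peaks.wavenumbers[0] == pytest.approx(1002.0, abs=1.0)

    def test_two_gaussians_sorted_by_wavenumber(self):
        y = _gauss(WN, 1450.0, 8.0, 1.0) + _gauss(WN, 700.0, 8.0, 0.6)
        s = rt.threshold_filter(rt.normalize_max(rt.Spectrum(WN, y)))
        peaks = rt.extract_peaks(s)
        assert len(peaks) == 2
        assert list(peaks.wavenumbers) == sorted(peaks.wavenumbers)

    def test_tumor_profile_lacks_benign_marker_peaks(self):
        profile = rt.default_profile("tumor", noise_sigma=0.0)
        s = rt.simulate_spectrum(profile, rt.SimulationConfig(
            amplitude_jitter=0.0, shift_jitter=0.0, seed=0))
        feats = rt.preprocess_ml(s, mode="2d")
        found = feats.wavenumbers[: feats.n_peaks]
        for missing in (662.0, 744.0, 752.0):
            assert np.all(np.abs(found - missing) > 4.0)

    def test_peaks_are_subset_of_strict_local_maxima(self):
        rng = np.random.default_rng(9)
        vals = rng.random(200)
        vals[17] = 1.0
        s = rt.Spectrum(400.0 + np.arange(200.0), vals)
        s = rt.threshold_filter(rt.normalize_max(s), tau=0.3)
        peaks = rt.extract_peaks(s, min_prominence=0.01)
        y = s.intensities
        # brute-force scan for strict interior local maxima
        strict = {s.wavenumbers[i] for i in range(1, len(y) - 1)
                  if y[i] > y[i - 1] and y[i] > y[i + 1]}
        assert set(peaks.wavenumbers) <= strict


class TestBuildFeatures:
    def test_pad_and_exact_fit(self):
        pk = PeakList(np.array([500.0, 600.0, 700.0]), np.array([0.4, 1.0, 0.5]))
        f = rt.build_features(pk, mode="1d", length=650)
        assert f.n_peaks == 3
        assert np.count_nonzero(f.intensities) == 3
        assert f.length == 650

    def test_overflow_keeps_top_by_intensity(self):
        rng = np.random.default_rng(13)
        n = 700
        wn = np.sort(rng.choice(np.arange(4000.0, 9000.0), size=n, replace=False))
        it = rng.uniform(0.3, 1.0, size=n)
        f = rt.build_features(PeakList(wn, it), mode="2d", length=650)
        # brute-force oracle: sort all peaks by (-intensity, wavenumber), keep 650
        order = sorted(range(n), key=lambda i: (-it[i], wn[i]))[:650]
        expect_wn = np.sort(wn[order])
        np.testing.assert_array_equal(f.wavenumbers, expect_wn)
        assert list(f.wavenumbers) == sorted(f.wavenumbers)

    def test_as_array_shapes(self):
        pk = PeakList(np.array([500.0]), np.array([1.0]))
        assert rt.build_features(pk, "1d", 10).as_array().shape == (10,)
        assert rt.build_features(pk, "2d", 10).as_array().shape == (10, 2)


class TestChains:
    def test_qm_chain_output_max_is_one(self):
        s = rt.simulate_spectrum(rt.default_profile("muscle"), seed=3)
        out = rt.preprocess_qm(s)
        assert out.intensities.max() == 1.0
        assert out.meta.baseline_corrected and out.meta.normalized

    def test_pure_polynomial_input_is_degenerate(self):
        s = rt.Spectrum(WN, _poly(WN, [1.0, 0.2, 0.1, -0.1, 0.4]))
        with pytest.raises(DegenerateSpectrumError):
            rt.preprocess_qm(s)

    def test_invariant_to_quartic_offset_and_scale(self):
        profile = rt.default_profile("dermis", noise_sigma=0.0)
        s = rt.simulate_spectrum(profile, rt.SimulationConfig(seed=8))
        shifted = s.with_intensities(
            3.0 * s.intensities + _poly(s.wavenumbers, [2.0, -1.0, 0.5, 0.3, -0.6]))
        a = rt.preprocess_qm(s).intensities
        b = rt.preprocess_qm(shifted).intensities
        assert np.abs(a - b).max() < 0.01

    def test_ml_chain_populates_planted_peaks_above_threshold(self):
        # 7 well-separated planted peaks above the cutoff, 3 below
        strong = [500.0, 620.0, 800.0, 1002.0, 1200.0, 1443.0, 1700.0]
        weak = [560.0, 900.0, 1550.0]
        peaks = [(c, 8.0, 0.6) for c in strong] + [(c, 8.0, 0.15) for c in weak]
        peaks[3] = (1002.0, 8.0, 1.0)  # normalisation anchor
        profile = rt.SyntheticTissueProfile(
            tissue_class=rt.TissueClass.TUMOR, peaks=peaks,
            baseline_coeffs=(0.2, 0.4, 0.1, 0.0, 0.1), noise_sigma=0.0)
        s = rt.simulate_spectrum(profile, rt.SimulationConfig(
            amplitude_jitter=0.0, shift_jitter=0.0, seed=0))
        feats = rt.preprocess_ml(s, mode="1d")
        assert feats.n_peaks == 7

    def test_ml_chain_deterministic(self):
        s = rt.simulate_spectrum(rt.default_profile("fat"), seed=17)
        a = rt.preprocess_ml(s, mode="2d")
        b = rt.preprocess_ml(s, mode="2d")
        np.testing.assert_array_equal(a.intensities, b.intensities)
        np.testing.assert_array_equal(a.wavenumbers, b.wavenumbers)

    def test_noiseless_two_peak_input_gives_two_slots(self):
        y = _gauss(WN, 800.0, 8.0, 1.0) + _gauss(WN, 1400.0, 8.0, 0.7) + 0.1
        feats = rt.preprocess_ml(rt.Spectrum(WN, y), mode="1d")
        assert feats.n_peaks == 2

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PreprocessConfig(threshold_tau=1.5)
        with pytest.raises(ValueError):
            PreprocessConfig(als_p=0.0)
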