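import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgrhythm.denoise import (NLMParams, butterworth_lowpass,
                               denoise_record, estimate_noise_sigma,
                               loess_baseline_remove, nlm_smooth)

FS = 500.0


def _tone(freq, n=5000, fs=FS, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / fs)


class TestButterworth:
    def test_dc_passthrough(self):
        x = np.full(2000, 3.7)
        out = butterworth_lowpass(x, FS, cutoff=50.0, order=4)
        np.testing.assert_allclose(out, x, atol=1e-9)

    def test_stopband_attenuation_100hz(self):
        x = _tone(100.0)
        out = butterworth_lowpass(x, FS, cutoff=50.0, order=4)
        assert np.sqrt(np.mean(out**2)) < 0.05 * np.sqrt(np.mean(x**2))

    def test_passband_preservation_5hz(self):
        x = _tone(5.0)
        out = butterworth_lowpass(x, FS, cutoff=50.0, order=4)
        assert np.sqrt(np.mean(out**2)) == pytest.approx(
            np.sqrt(np.mean(x**2)), rel=0.02)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(1000), rng.standard_normal(1000)
        lhs = butterworth_lowpass(x + y, FS)
        rhs = butterworth_lowpass(x, FS) + butterworth_lowpass(y, FS)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            butterworth_lowpass(np.zeros(100), FS, cutoff=300.0)


class TestLoess:
    def test_zero_signal_fixed_point(self):
        det, base = loess_baseline_remove(np.zeros(1000), FS)
        np.testing.assert_allclose(det, 0.0, atol=1e-12)
        np.testing.assert_allclose(base, 0.0, atol=1e-12)

    def test_captures_slow_wander(self):
        x = _tone(0.3)
        det, _ = loess_baseline_remove(x, FS)
        assert np.sqrt(np.mean(det**2)) < 0.1

    def test_recovers_injected_wander(self, sr_record):
        record, _ = sr_record
        wander = 0.4 * _tone(0.3)
        det, base = loess_baseline_remove(record.lead("II") + wander, FS)
        assert np.corrcoef(base, wander)[0, 1] > 0.95

    def test_linearity_without_robustification(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(2000), rng.standard_normal(2000)
        lx, _ = loess_baseline_remove(x, FS, robust_iterations=0)
        ly, _ = loess_baseline_remove(y, FS, robust_iterations=0)
        lxy, _ = loess_baseline_remove(x + y, FS, robust_iterations=0)
        np.testing.assert_allclose(lxy, lx + ly, atol=1e-8)

    def test_span_too_small_rejected(self):
        with pytest.raises(ValueError, match="span"):
            loess_baseline_remove(np.zeros(100), FS, span=0.0)


class TestNoiseSigma:
    def test_constant_and_ramp_give_zero(self):
        assert estimate_noise_sigma(np.full(100, 2.5)) == 0.0
        assert estimate_noise_sigma(np.linspace(0, 5, 100)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_unit_gaussian_calibration(self):
        rng = np.random.default_rng(42)
        sigma = estimate_noise_sigma(rng.standard_normal(5000))
        assert 0.95 <= sigma <= 1.05

    @given(c=st.floats(-10, 10, allow_nan=False).filter(lambda v: v != 0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(500)
        assert estimate_noise_sigma(c * x) == pytest.approx(
            abs(c) * estimate_noise_sigma(x), rel=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_sigma(np.array([1.0, 2.0]))


class TestNLM:
    def test_constant_signal_unchanged(self):
        x = np.full(200, 1.5)
        out = nlm_smooth(x, NLMParams(), sigma_hat=0.1)
        np.testing.assert_allclose(out, x, atol=1e-12)

    def test_zero_sigma_returns_input(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(100)
        np.testing.assert_array_equal(nlm_smooth(x, NLMParams(), 0.0), x)

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(800)
        out = nlm_smooth(x, NLMParams(search_mode="windowed",
                                      search_half_width=100), sigma_hat=0.5)
        assert out.min() >= x.min() - 1e-12
        assert out.max() <= x.max() + 1e-12

    def test_denoises_repeated_beats(self, sr_record):
        """Averaging across repeated beats cuts the noise MSE substantially.

        At the default bandwidth (lambda = 1.5 sigma) the gain is bounded by
        low-amplitude smooth waves (P/T) whose patches resemble baseline;
        R peaks themselves denoise nearly perfectly.  In the full pipeline
        sigma is estimated after low-pass filtering, so lambda is far
        smaller and this effect vanishes.
        """
        record, _ = sr_record
        clean = record.lead("II")
        rng = np.random.default_rng(12)
        noisy = clean + 0.05 * rng.standard_normal(clean.size)
        out = nlm_smooth(noisy, NLMParams(), sigma_hat=0.05)
        mse_in = np.mean((noisy - clean) ** 2)
        mse_out = np.mean((out - clean) ** 2)
        assert mse_out < 0.65 * mse_in

    def test_flat_regions_average_to_truth(self):
        """On structureless signal NLM approaches the global mean."""
        rng = np.random.default_rng(0)
        noise = 0.05 * rng.standard_normal(3000)
        out = nlm_smooth(noise, NLMParams(), sigma_hat=0.05)
        assert np.mean(out**2) < 0.01 * np.mean(noise**2)

    def test_signal_shorter_than_patch_rejected(self):
        with pytest.raises(ValueError, match="patch"):
            nlm_smooth(np.zeros(5), NLMParams(patch_half_width=10), 1.0)


class TestDenoiseRecord:
    def test_preserves_shape_and_order(self, noisy_sr):
        _, noisy, _ = noisy_sr
        out, report = denoise_record(
            noisy, params=NLMParams(search_mode="windowed",
                                    search_half_width=200))
        assert out.signal.shape == noisy.signal.shape
        assert report.stage_order == ("butterworth", "loess", "nlm")
        assert all(s >= 0 for s in report.sigma_hat.values())

    def test_near_identity_on_clean_record(self, sr_record):
        record, _ = sr_record
        out, _ = denoise_record(
            record, params=NLMParams(search_mode="windowed",
                                     search_half_width=200))
        r_amp = record.lead("II").max()
        assert np.max(np.abs(out.signal - record.signal)) < 0.05 * r_amp

    def test_zero_phase_alignment(self, noisy_sr):
        """Cross-correlation of clean vs denoised lead II peaks at lag 0."""
        clean, noisy, _ = noisy_sr
        out, _ = denoise_record(
            noisy, params=NLMParams(search_mode="windowed",
                                    search_half_width=200))
        a = clean.lead("II") - clean.lead("II").mean()
        b = out.lead("II") - out.lead("II").mean()
        xc = np.correlate(a, b, mode="full")
        assert abs(int(np.argmax(xc)) - (a.size - 1)) == 0
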