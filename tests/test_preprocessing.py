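import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from apvpeaks.io import Spectrum
from apvpeaks.models import PeakParams, mapv_eval
from apvpeaks.preprocessing import (
    SureInputs,
    WaveletShrinkageConfig,
    correct_baseline,
    estimate_baseline,
    estimate_noise_sigma,
    preprocess,
    select_sure_threshold,
    smooth_spectrum,
    sure_risk,
)


class TestNoiseSigma:
    def test_zero_dispersion(self):
        assert estimate_noise_sigma(np.full(10, 3.0)) == 0.0

    def test_hand_value(self):
        # median |x - 0| = 1 -> 1/0.6745
        assert estimate_noise_sigma(np.array([-1.0, 0.0, 1.0])) == pytest.approx(
            1 / 0.6745
        )

    def test_monte_carlo_consistency(self):
        x = np.random.default_rng(7).normal(0, 2.5, size=100_000)
        assert estimate_noise_sigma(x) == pytest.approx(2.5, rel=0.02)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            estimate_noise_sigma(np.array([]))


class TestSureRisk:
    def test_identity_endpoint(self, rng):
        x = rng.normal(size=50)
        inp = SureInputs(np.abs(x), 1.3)
        assert sure_risk(0.0, inp) == pytest.approx(50 * 1.3**2)

    def test_kill_all_endpoint(self, rng):
        x = np.abs(rng.normal(size=50))
        inp = SureInputs(x, 0.7)
        t = x.max() + 1.0
        assert sure_risk(t, inp) == pytest.approx((x**2).sum() - 50 * 0.7**2)

    def test_hand_value(self):
        # x=[1,3], sigma=1, t=2: 2 + (1+4) - 2*1 = 5
        assert sure_risk(2.0, SureInputs(np.array([1.0, 3.0]), 1.0)) == 5.0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            sure_risk(-1.0, SureInputs(np.array([1.0]), 1.0))


class TestSelectSureThreshold:
    def test_brute_force_grid_oracle(self, rng):
        for _ in range(200):
            d = rng.integers(1, 9)
            x = np.abs(rng.normal(0, 1, size=d)) * rng.uniform(0.5, 3)
            inp = SureInputs(x, float(rng.uniform(0.3, 2.0)))
            t_star = select_sure_threshold(inp)
            grid = np.linspace(0, x.max() * 1.2 + 1e-9, 10_000)
            grid_risks = np.array([sure_risk(t, inp) for t in grid])
            assert sure_risk(t_star, inp) <= grid_risks.min() + 1e-9

    def test_pure_noise_never_worse_than_identity(self, rng):
        x = np.abs(rng.normal(0, 1, size=300))
        inp = SureInputs(x, 1.0)
        t = select_sure_threshold(inp)
        assert sure_risk(t, inp) <= sure_risk(0.0, inp)
        assert t > 0

    def test_large_coefficients_survive(self, rng):
        noise = np.abs(rng.normal(0, 1, size=100))
        big = np.full(5, 50.0)
        inp = SureInputs(np.concatenate([noise, big]), 1.0)
        t = select_sure_threshold(inp)
        assert t < 50.0  # the 5 signal coefficients are not zeroed


class TestSmoothSpectrum:
    @staticmethod
    def _clean_spectrum(n=1200):
        mz = np.linspace(100, 220, n)
        y = np.zeros(n)
        for alpha, h in [(120, 100), (150, 60), (185, 80)]:
            y += mapv_eval(mz, PeakParams(h, alpha, 2.0, 3.0, 0.3, 0.5))
        return mz, y

    def test_zero_spectrum_stays_zero(self):
        mz = np.linspace(0, 10, 400)
        s = Spectrum(mz, np.zeros(400))
        out = smooth_spectrum(s)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)

    def test_noise_reduction(self, rng):
        mz, clean = self._clean_spectrum()
        noisy = clean + rng.normal(0, 5.0, clean.size)
        out = smooth_spectrum(Spectrum(mz, noisy))
        rmse_raw = np.sqrt(np.mean((noisy - clean) ** 2))
        rmse_smooth = np.sqrt(np.mean((out.intensity - clean) ** 2))
        assert rmse_smooth < rmse_raw

    def test_shift_robustness(self, rng):
        mz, clean = self._clean_spectrum()
        noisy = clean + rng.normal(0, 5.0, clean.size)
        rmses = []
        for shift in range(5):
            sh_noisy = np.roll(noisy, shift)
            sh_clean = np.roll(clean, shift)
            out = smooth_spectrum(Spectrum(mz, sh_noisy))
            rmses.append(np.sqrt(np.mean((out.intensity - sh_clean) ** 2)))
        rmses = np.array(rmses)
        assert np.ptp(rmses) / rmses.mean() < 0.15

    def test_near_idempotent_on_noiseless(self):
        mz, clean = self._clean_spectrum()
        once = smooth_spectrum(Spectrum(mz, clean))
        twice = smooth_spectrum(once)
        rel = np.linalg.norm(twice.intensity - once.intensity) / np.linalg.norm(
            once.intensity
        )
        assert rel < 0.01

    def test_mz_and_length_preserved(self, rng):
        mz, clean = self._clean_spectrum(997)  # not divisible by n_segments
        out = smooth_spectrum(Spectrum(mz, clean + rng.normal(0, 1, 997)))
        assert len(out) == 997
        np.testing.assert_array_equal(out.mz, mz)
        assert out.metadata["stage"] == "smoothed"

    def test_too_short_rejected(self):
        s = Spectrum(np.arange(6, dtype=float), np.zeros(6))
        with pytest.raises(ValueError):
            smooth_spectrum(s, WaveletShrinkageConfig(n_segments=4))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            WaveletShrinkageConfig(n_segments=0)
        with pytest.raises(ValueError):
            WaveletShrinkageConfig(threshold_rule="hard")


class TestBaseline:
    def test_increasing_spectrum_flat_baseline(self):
        s = Spectrum(np.arange(4, dtype=float), np.array([1.0, 2, 3, 4]))
        np.testing.assert_array_equal(estimate_baseline(s), [1, 1, 1, 1])

    def test_decreasing_spectrum_followed(self):
        s = Spectrum(np.arange(4, dtype=float), np.array([4.0, 3, 2, 1]))
        np.testing.assert_array_equal(estimate_baseline(s), [4, 3, 2, 1])

    def test_hand_trace(self):
        s = Spectrum(np.arange(5, dtype=float), np.array([5.0, 3, 6, 2, 4]))
        np.testing.assert_array_equal(estimate_baseline(s), [5, 3, 3, 2, 2])

    def test_correct_baseline_hand_trace(self):
        s = Spectrum(np.arange(5, dtype=float), np.array([5.0, 3, 6, 2, 4]))
        out = correct_baseline(s, np.array([5.0, 3, 3, 2, 2]))
        np.testing.assert_array_equal(out.intensity, [0, 0, 3, 0, 2])
        assert out.metadata["stage"] == "baseline_corrected"

    def test_zero_baseline_identity(self, rng):
        y = np.abs(rng.normal(size=20))
        s = Spectrum(np.arange(20, dtype=float), y)
        np.testing.assert_array_equal(correct_baseline(s, np.zeros(20)).intensity, y)

    def test_self_subtraction(self):
        s = Spectrum(np.arange(4, dtype=float), np.array([4.0, 3, 2, 1]))
        out = correct_baseline(s, estimate_baseline(s))
        np.testing.assert_array_equal(out.intensity, np.zeros(4))

    def test_length_mismatch(self):
        s = Spectrum(np.arange(4, dtype=float), np.ones(4))
        with pytest.raises(ValueError):
            correct_baseline(s, np.zeros(3))

    @settings(max_examples=200, deadline=None)
    @given(
        arrays(np.float64, st.integers(2, 60),
               elements=st.floats(0, 1e6, allow_nan=False))
    )
    def test_baseline_non_increasing_property(self, y):
        s = Spectrum(np.arange(y.size, dtype=float), y)
        b = estimate_baseline(s)
        assert np.all(np.diff(b) <= 0)
        assert np.all(b <= np.minimum.accumulate(y) + 1e-12)

    def test_recurrence_oracle_random(self, rng):
        for _ in range(1000):
            y = rng.uniform(0, 100, size=rng.integers(2, 40))
            s = Spectrum(np.arange(y.size, dtype=float), y)
            b = estimate_baseline(s)
            expected = np.empty_like(y)
            expected[0] = y[0]
            for i in range(1, y.size):
                expected[i] = min(expected[i - 1], y[i])
            np.testing.assert_array_equal(b, expected)


class TestFullPreprocess:
    def test_peak_positions_preserved(self):
        mz = np.linspace(100, 220, 2400)
        clean = np.zeros(mz.size)
        truth_alphas = [120.0, 150.0, 185.0]
        for alpha in truth_alphas:
            clean += mapv_eval(mz, PeakParams(100, alpha, 2.0, 2.0, 0.2, 0.2))
        out = preprocess(Spectrum(mz, clean))
        dx = mz[1] - mz[0]
        for alpha in truth_alphas:
            win = (mz > alpha - 5) & (mz < alpha + 5)
            summit = mz[win][np.argmax(out.intensity[win])]
            assert abs(summit - alpha) <= dx + 1e-9
        assert out.metadata["stage"] == "baseline_corrected"
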