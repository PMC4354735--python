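import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

from sgleeg.features import (FeatureConfig, FeatureExtractionError, TrialSet,
                             _log_energy_entropy, _shannon_entropy,
                             _teager_kaiser, ar_coefficients, band_power,
                             extract_fused, resample_trial, time_stats,
                             wavelet_features)


class TestBandPower:
    def test_zero_signal_gives_zero_powers(self):
        out = band_power(np.zeros(400), fs=100.0)
        assert out.shape == (5,)
        assert np.allclose(out, 0.0)

    @pytest.mark.parametrize("method", ["welch", "periodogram"])
    def test_alpha_band_dominates_for_10hz_sinusoid(self, method):
        t = np.arange(400) / 100.0
        x = np.sin(2 * np.pi * 10.0 * t)
        out = band_power(x, fs=100.0, psd_method=method)
        # independent check: direct periodogram integration of the same signal
        f, pxx = sps.periodogram(x, fs=100.0)
        df = f[1] - f[0]
        ref = [pxx[(f >= lo) & (f < hi)].sum() * df
               for lo, hi in ((2, 4), (4, 8), (8, 12), (12, 18), (18, 30))]
        assert ref[2] / sum(ref) > 0.95
        assert out[2] / out.sum() > 0.95

    def test_output_length_matches_band_count(self):
        x = np.random.default_rng(0).standard_normal(400)
        assert band_power(x, 100.0).shape == (5,)
        assert band_power(x, 100.0, bands=((1, 5), (5, 20))).shape == (2,)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_power(np.ones(400), fs=100.0, bands=((40.0, 60.0),))

    def test_short_signal_error_names_minimum_length(self):
        with pytest.raises(ValueError, match="100"):
            band_power(np.ones(50), fs=100.0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=50.0),
           st.integers(min_value=0, max_value=100))
    def test_power_scales_quadratically_with_amplitude(self, a, seed):
        x = np.random.default_rng(seed).standard_normal(400)
        base = band_power(x, 100.0)
        scaled = band_power(a * x, 100.0)
        assert np.allclose(scaled, a * a * base, rtol=1e-9, atol=1e-12)


class TestTimeStats:
    def test_constant_signal(self):
        assert np.allclose(time_stats(np.full(10, 3.5)), [3.5, 0, 0, 0])

    def test_ramp(self):
        x = 0.7 * np.arange(20)
        out = time_stats(x)
        assert out[2] == pytest.approx(0.7)
        assert out[3] == pytest.approx(0.0, abs=1e-12)

    def test_alternating_four_sample_vector(self):
        # hand computation: diffs are (-2, 2, -2); second diffs (4, -4)
        out = time_stats(np.array([1.0, -1.0, 1.0, -1.0]))
        assert out[0] == pytest.approx(0.0)
        assert out[2] == pytest.approx(2.0)
        assert out[3] == pytest.approx(4.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            time_stats(np.array([1.0, 2.0]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.floats(min_value=-100, max_value=100),
           st.integers(min_value=0, max_value=50))
    def test_shift_changes_only_the_mean(self, c, seed):
        x = np.random.default_rng(seed).standard_normal(64)
        base = time_stats(x)
        shifted = time_stats(x + c)
        assert shifted[0] == pytest.approx(base[0] + c, abs=1e-9)
        assert np.allclose(shifted[1:], base[1:], atol=1e-12)


def _yule_walker_oracle(x, order):
    """AR coefficients solved directly from empirical autocovariances."""
    x = x - x.mean()
    n = x.size
    r = np.array([x[:n - k] @ x[k:] / n for k in range(order + 1)])
    from scipy.linalg import solve_toeplitz
    return solve_toeplitz(r[:-1], r[1:])


class TestARCoefficients:
    def test_recovers_ar1_coefficient(self):
        rng = np.random.default_rng(42)
        x = np.empty(10000)
        x[0] = rng.standard_normal()
        for i in range(1, x.size):
            x[i] = 0.5 * x[i - 1] + rng.standard_normal()
        for method in ("burg", "yule_walker"):
            coef = ar_coefficients(x, order=6, ar_method=method)
            assert abs(coef[0] - 0.5) < 0.05
            assert np.all(np.abs(coef[1:]) < 0.1)
        # agreement with the autocovariance-solved oracle
        oracle = _yule_walker_oracle(x, 6)
        assert np.allclose(ar_coefficients(x, 6, "burg"), oracle, atol=0.02)

    def test_white_noise_coefficients_near_zero(self):
        x = np.random.default_rng(7).standard_normal(10000)
        coef = ar_coefficients(x, order=6)
        assert np.all(np.abs(coef) < 0.05)
        assert np.all(np.abs(_yule_walker_oracle(x, 6)) < 0.05)

    def test_output_length_equals_order(self):
        x = np.random.default_rng(0).standard_normal(400)
        assert ar_coefficients(x, order=6).shape == (6,)
        assert ar_coefficients(x, order=3).shape == (3,)

    def test_constant_signal_rejected(self):
        with pytest.raises(ValueError, match="degenerate|constant"):
            ar_coefficients(np.ones(100), order=6)


class TestWaveletFeatures:
    def test_default_dimension_is_55(self):
        x = np.random.default_rng(0).standard_normal(400)
        assert wavelet_features(x).shape == (55,)

    def test_terminal_mode_dimension_is_35(self):
        x = np.random.default_rng(0).standard_normal(400)
        cfg = FeatureConfig(wavelet_mode="terminal")
        assert wavelet_features(x, cfg).shape == (35,)

    def test_zero_signal(self):
        out = wavelet_features(np.zeros(400))
        energies = out[:7]
        rest = out[7:].reshape(12, 4)
        assert np.allclose(energies, 0.0)
        assert np.allclose(rest[:, 0], 0.0)   # Shannon entropy, 0*ln0 := 0
        assert np.allclose(rest[:, 2:], 0.0)  # TK mean and variance

    def test_single_nonzero_coefficient_entropy(self):
        # degenerate distribution at the coefficient level
        c = np.zeros(16)
        c[5] = 3.0
        assert _shannon_entropy(c) == pytest.approx(0.0)
        assert float((c * c).sum()) == pytest.approx(9.0)

    def test_shannon_entropy_scale_invariant(self):
        c = np.random.default_rng(3).standard_normal(32)
        for a in (0.1, -2.0, 1e3):
            assert _shannon_entropy(a * c) == pytest.approx(
                _shannon_entropy(c), rel=1e-9)

    def test_teager_kaiser_definition(self):
        c = np.array([1.0, 2.0, 3.0, 1.0])
        psi = np.array([2.0 * 2 - 1 * 3, 3.0 * 3 - 2 * 1])
        mean, var = _teager_kaiser(c)
        assert mean == pytest.approx(psi.mean())
        assert var == pytest.approx(psi.var())

    def test_log_energy_entropy_guard(self):
        c = np.zeros(4)
        out = _log_energy_entropy(c, 1e-12)
        assert np.isfinite(out)

    def test_too_short_error_names_required_length(self):
        with pytest.raises(ValueError, match="64"):
            wavelet_features(np.ones(32))


class TestExtractFused:
    def _trials(self, n_trials, n_channels, n_samples=400, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((n_trials, n_channels, n_samples))
        labels = np.arange(n_trials) % 2 + 1
        return TrialSet(trials=data, labels=labels, fs=100.0)

    def test_59_channels_yield_4130_columns(self):
        fm = extract_fused(self._trials(2, 59))
        assert fm.values.shape == (2, 59 * 70)
        assert fm.d == 70
        gs = fm.groups
        assert gs.n_groups == 59
        assert np.all(gs.sizes == 70)

    def test_single_channel_is_70_dimensional(self):
        fm = extract_fused(self._trials(2, 1))
        assert fm.values.shape == (2, 70)
        assert fm.groups.n_groups == 1

    def test_group_blocks_contiguous_and_exhaustive(self):
        fm = extract_fused(self._trials(2, 3))
        assert np.array_equal(fm.group_index, np.repeat(np.arange(3), 70))
        assert len(fm.feature_labels) == 3 * 70

    def test_empty_trials_rejected(self):
        with pytest.raises(ValueError):
            TrialSet(trials=np.empty((0, 3, 400)), labels=np.empty(0),
                     fs=100.0)

    def test_degenerate_channel_error_carries_context(self):
        data = np.random.default_rng(0).standard_normal((2, 2, 400))
        data[1, 1] = 0.0  # constant channel breaks the AR fit
        ts = TrialSet(trials=data, labels=np.array([1, 2]), fs=100.0)
        with pytest.raises(FeatureExtractionError, match="trial 1, channel"):
            extract_fused(ts)


class TestResample:
    def test_4000_at_1khz_becomes_400_at_100hz(self):
        x = np.random.default_rng(0).standard_normal((3, 4000))
        out = resample_trial(x, 1000.0, 100.0)
        assert out.shape == (3, 400)

    def test_identity_when_rates_equal(self):
        x = np.random.default_rng(0).standard_normal((2, 100))
        assert np.array_equal(resample_trial(x, 100.0, 100.0), x)

    def test_dc_channel_stays_dc(self):
        x = np.full((1, 4000), 2.5)
        out = resample_trial(x, 1000.0, 100.0)
        assert np.allclose(out, 2.5, atol=1e-6)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="upsampling"):
            resample_trial(np.ones((1, 100)), 100.0, 200.0)
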