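"""PCNR statistic, Monte Carlo calibration, PI, lag, spectrum."""

import numpy as np
import pytest
from conftest import lag_oracle, pcnr_oracle, sg_oracle

from veinpulse.pulsatility import (calibrate_null, dominant_frequency, pcnr,
                                   power_spectrum, pulsatility_index,
                                   smooth_waveform, temporal_lag)
from veinpulse.velocimetry import VelocityWaveform


class TestSmoothing:
    def test_cubic_reproduced_exactly(self):
        """An order-3 filter passes any cubic unchanged."""
        t = np.linspace(-1, 1, 38)
        x = 0.3 * t ** 3 - t ** 2 + 0.5 * t + 2.0
        assert np.allclose(smooth_waveform(x), x, atol=1e-10)

    def test_constant_preserved(self):
        x = np.full(20, 4.2)
        assert np.allclose(smooth_waveform(x), x)

    def test_matches_polyfit_oracle(self, rng):
        x = rng.standard_normal(38)
        assert np.allclose(smooth_waveform(x), sg_oracle(x), atol=1e-10)

    def test_wrap_mode_sinusoid_attenuation(self):
        """Under circular filtering a single harmonic is scaled by the
        kernel's frequency response, computed here from explicitly derived
        least-squares coefficients."""
        n = 38
        t = np.arange(n)
        x = np.sin(2 * np.pi * t / n)
        # explicit SG kernel: centre row of the LSQ smoothing matrix
        A = np.vander(np.arange(-7, 8), 4, increasing=True)
        kernel = (A @ np.linalg.pinv(A))[7]
        gain = kernel @ np.cos(2 * np.pi * np.arange(-7, 8) / n)
        out = smooth_waveform(x, mode="wrap")
        assert np.allclose(out, gain * x, atol=1e-10)

    def test_short_waveform_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            smooth_waveform(np.zeros(10))


class TestPcnr:
    def test_constant_waveform_zero(self):
        stats = pcnr(np.full(38, 2.5))
        assert stats.pcnr == 0.0 and stats.delta_v == 0.0

    def test_pure_cubic_infinite_flag(self):
        """Zero residual with nonzero range is unambiguous signal."""
        t = np.linspace(-1, 1, 38)
        stats = pcnr(t ** 3 - t)
        assert np.isinf(stats.pcnr) and stats.delta_v > 0

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            x = rng.standard_normal(38)
            got = pcnr(x)
            exp_pcnr, exp_dv, exp_sd = pcnr_oracle(x)
            assert got.pcnr == pytest.approx(exp_pcnr, rel=1e-12)
            assert got.delta_v == pytest.approx(exp_dv, rel=1e-12)
            assert got.res_sd == pytest.approx(exp_sd, rel=1e-12)

    def test_scale_and_offset_invariance(self, rng):
        x = rng.standard_normal(38)
        base = pcnr(x).pcnr
        assert pcnr(5.0 * x + 3.0).pcnr == pytest.approx(base, rel=1e-10)
        assert pcnr(0.01 * x - 7.0).pcnr == pytest.approx(base, rel=1e-10)


class TestCalibration:
    def test_threshold_near_published_value(self, calibration_38):
        """The 99th percentile of PCNR on Gaussian noise at N=38 is ~3.9."""
        assert 3.6 <= calibration_38.threshold <= 4.2

    def test_insensitive_to_n_phases(self, calibration_38):
        thr = {n: calibrate_null(n_phases=n, n_reps=20_000, seed=77).threshold
               for n in (33, 45)}
        for v in thr.values():
            assert abs(v - calibration_38.threshold) \
                / calibration_38.threshold < 0.05

    def test_noise_scale_invariance_is_algebraic(self, rng):
        """PCNR(sigma * noise) == PCNR(noise) exactly, so the calibrated
        threshold cannot depend on the noise SD."""
        x = rng.standard_normal(38)
        assert pcnr(10.0 * x).pcnr == pytest.approx(pcnr(x).pcnr, rel=1e-12)

    def test_type_one_error_rate(self, calibration_38, rng):
        """Fraction of pure-noise waveforms crossing the alpha=0.01
        threshold stays within binomial error of 1%."""
        n_trials = 4000
        X = rng.standard_normal((n_trials, 38))
        flagged = np.mean([pcnr(x).pcnr > calibration_38.threshold
                           for x in X])
        se = np.sqrt(0.01 * 0.99 / n_trials)
        assert abs(flagged - 0.01) < 3 * se

    def test_detection_power_monotone_in_snr(self, calibration_38):
        """With common noise draws, the detection rate is non-decreasing in
        the pulse-amplitude-to-noise ratio."""
        rng = np.random.default_rng(99)
        n, reps = 38, 300
        t = np.arange(n)
        signal = np.sin(2 * np.pi * t / n)
        noise = rng.standard_normal((reps, n))
        rates = []
        for amp in (0.0, 0.5, 1.0, 2.0, 4.0):
            X = amp * signal + noise
            rates.append(np.mean([pcnr(x).pcnr > calibration_38.threshold
                                  for x in X]))
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert rates[0] < 0.05 and rates[-1] > 0.9

    def test_bad_arguments(self):
        with pytest.raises(ValueError):
            calibrate_null(n_reps=10)
        with pytest.raises(ValueError):
            calibrate_null(alpha=1.5)


class TestPulsatilityIndex:
    def test_constant_waveform_zero(self):
        assert pulsatility_index(np.full(38, 1.0)) == 0.0

    def test_scale_invariant_not_offset_invariant(self, rng):
        x = 1.0 + 0.2 * np.sin(2 * np.pi * np.arange(38) / 38)
        assert pulsatility_index(3.0 * x) == \
            pytest.approx(pulsatility_index(x), rel=1e-12)
        assert pulsatility_index(x + 1.0) != \
            pytest.approx(pulsatility_index(x), rel=1e-3)

    def test_sinusoid_matches_filter_oracle(self):
        """v = 1 + 0.15 sin: PI equals the filtered range over mean |v|,
        with the range taken through the explicit polyfit oracle; the
        result sits just under the unattenuated value of 0.30."""
        t = np.arange(38)
        x = 1.0 + 0.15 * np.sin(2 * np.pi * t / 38)
        expected = np.ptp(sg_oracle(x)) / np.mean(np.abs(x))
        got = pulsatility_index(x)
        assert got == pytest.approx(expected, abs=1e-12)
        assert 0.27 < got <= 0.30

    def test_zero_mean_speed_is_error(self):
        with pytest.raises(ValueError, match="PI"):
            pulsatility_index(np.zeros(38))


class TestTemporalLag:
    def _wave(self, values):
        return VelocityWaveform(values=values, phase_duration=23.1)

    def test_self_lag_zero(self, rng):
        x = rng.standard_normal(38)
        lag, lag_ms = temporal_lag(self._wave(x), self._wave(x))
        assert lag == 0 and lag_ms == 0.0

    def test_known_shift_and_ms_mapping(self, rng):
        ref = np.sin(2 * np.pi * np.arange(38) / 38) + \
            0.3 * rng.standard_normal(38)
        w = np.roll(ref, 3)
        lag, lag_ms = temporal_lag(self._wave(w), self._wave(ref))
        assert lag == 3
        assert lag_ms == pytest.approx(69.3)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(25):
            ref = rng.standard_normal(19)
            w = np.roll(ref, int(rng.integers(19))) \
                + 0.1 * rng.standard_normal(19)
            lag, _ = temporal_lag(self._wave(w), self._wave(ref))
            assert lag == lag_oracle(w, ref)

    def test_antiphase_single_harmonic(self):
        ref = np.sin(2 * np.pi * np.arange(38) / 38)
        lag, _ = temporal_lag(self._wave(-ref), self._wave(ref))
        assert abs(lag) == 19  # half a cycle, at the range boundary

    def test_negative_lags_resolved(self, rng):
        ref = np.sin(2 * np.pi * np.arange(38) / 38) \
            + 0.2 * rng.standard_normal(38)
        w = np.roll(ref, -4)
        lag, lag_ms = temporal_lag(self._wave(w), self._wave(ref))
        assert lag == -4 and lag_ms == pytest.approx(-92.4)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            temporal_lag(self._wave(np.ones(38)),
                         self._wave(np.sin(np.arange(38.0))))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            temporal_lag(self._wave(np.sin(np.arange(38.0))),
                         self._wave(np.sin(np.arange(33.0))))

    def test_parabolic_refinement_brackets_integer_peak(self):
        ref = np.sin(2 * np.pi * np.arange(38) / 38)
        w = np.roll(ref, 2)
        lag, _ = temporal_lag(self._wave(w), self._wave(ref), refine=True)
        assert abs(lag - 2.0) <= 0.5


class TestSpectrum:
    def test_single_harmonic_dominates_at_one(self):
        x = np.sin(2 * np.pi * np.arange(38) / 38)
        assert dominant_frequency(x) == 1

    def test_constant_has_no_ac_power(self):
        _, amp = power_spectrum(np.full(38, 3.0))
        assert np.all(amp[1:] < 1e-10)

    def test_linearity_of_bin_amplitudes(self):
        t = np.arange(38)
        x = 2.0 * np.sin(2 * np.pi * t / 38) + \
            1.0 * np.sin(2 * np.pi * 2 * t / 38)
        _, amp = power_spectrum(x)
        assert amp[1] / amp[2] == pytest.approx(2.0, rel=1e-9)
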