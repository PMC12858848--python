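import numpy as np
import pytest

from multistress.features import (
    decompose_eda,
    detect_r_peaks,
    interpolate_cortisol,
    moving_average,
    pulse_features,
    wavelet_power_spectrum,
)
from multistress.simulate import (
    Channel,
    SparseChannel,
    beat_times_from_hr,
    simulate_ecg,
    simulate_gsr,
    simulate_rap,
)


class TestRPeakDetection:
    def test_sixty_bpm_gives_one_beat_per_second(self):
        ecg = simulate_ecg(60, 60, 128, 0.0, 1)
        beats = detect_r_peaks(ecg)
        assert 59 <= len(beats) <= 61
        assert beats.mean_hr == pytest.approx(60, abs=1)

    @pytest.mark.parametrize("hr", [89, 107])
    def test_quiz_range_heart_rates_recovered(self, hr):
        ecg = simulate_ecg(60, hr, 128, 0.02, 2)
        assert detect_r_peaks(ecg).mean_hr == pytest.approx(hr, abs=2)

    def test_offset_invariance(self):
        ecg = simulate_ecg(30, 72, 128, 0.0, 3)
        shifted = Channel(ecg.samples + 5.0, ecg.sampling_rate, ecg.units)
        assert np.array_equal(
            detect_r_peaks(ecg).r_peak_times_s, detect_r_peaks(shifted).r_peak_times_s
        )

    def test_flat_and_empty_signals_give_empty_series(self):
        assert len(detect_r_peaks(Channel(np.zeros(6400), 128, "mV"))) == 0
        assert len(detect_r_peaks(Channel(np.array([]), 128, "mV"))) == 0

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            detect_r_peaks(Channel(np.zeros(100), 32, "mV"))


class TestEdaDecomposition:
    def test_constant_input_all_tonic_no_events(self):
        ch = Channel(np.full(128 * 30, 4.2), 128, "uS")
        eda = decompose_eda(ch)
        assert np.allclose(eda.tonic, 4.2)
        assert eda.scr_events == []

    def test_additivity_to_machine_precision(self):
        ch = simulate_gsr(120, 5.0, 8.0, 0.4, 5)
        eda = decompose_eda(ch)
        assert np.allclose(eda.tonic + eda.phasic, ch.samples, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 3, 8])
    def test_event_count_recovered_within_ten_percent(self, seed):
        ch, events = simulate_gsr(600, 5.0, 6.0, 0.4, seed, return_events=True)
        eda = decompose_eda(ch)
        onsets = np.sort([e[0] for e in events])
        resolvable = 1 + int((np.diff(onsets) >= 0.5).sum())
        assert len(eda.scr_events) == pytest.approx(resolvable, rel=0.10)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            decompose_eda(Channel(np.zeros(100), 4, "uS"), tonic_cutoff_Hz=3.0)


class TestPulseFeatures:
    def test_crest_time_recovered_within_one_sample(self):
        fs = 64.0
        rap = simulate_rap(60, 60, 150.0, 1.0, 5, fs)
        beats = beat_times_from_hr(60, 60)
        pf = pulse_features(rap, beats)
        assert len(pf.crest_time_ms) >= 55
        assert pf.mean_crest_time_ms == pytest.approx(150.0, abs=1000.0 / fs)

    def test_amplitude_linearity(self):
        beats = beat_times_from_hr(30, 60)
        a1 = pulse_features(simulate_rap(30, 60, 150.0, 1.0, 5), beats).amplitude
        a2 = pulse_features(simulate_rap(30, 60, 150.0, 2.0, 5), beats).amplitude
        assert np.allclose(a2, 2 * a1, rtol=1e-6)

    def test_landmark_ordering_within_pulse(self):
        rap = simulate_rap(30, 60, 150.0, 1.0, 5)
        pf = pulse_features(rap, beat_times_from_hr(30, 60))
        ok = ~np.isnan(pf.t_times_s) & ~np.isnan(pf.d_times_s)
        assert ok.sum() > 0.8 * len(pf.p_times_s)
        assert np.all(pf.p_times_s[ok] < pf.t_times_s[ok])
        assert np.all(pf.t_times_s[ok] < pf.d_times_s[ok])

    def test_missing_later_waves_flagged_but_ct_returned(self):
        # a bare triangular pulse: percussion only, no tidal/dicrotic waves
        fs = 64.0
        t = np.arange(int(2 * fs)) / fs
        x = np.clip(1 - np.abs(t - 0.15) / 0.15, 0, None)
        pf = pulse_features(Channel(x, fs, "dI/I0"), np.array([0.0]))
        assert len(pf.crest_time_ms) == 1
        assert pf.crest_time_ms[0] == pytest.approx(150.0, abs=1000.0 / fs)
        assert np.isnan(pf.d_times_s[0])

    def test_pulse_count_matches_ecg_beat_count(self):
        hr = np.full(60, 75.0)
        rap = simulate_rap(60, hr, 150.0, 1.0, 1)
        ecg = simulate_ecg(60, hr, 128, 0.0, 1)
        beats = detect_r_peaks(ecg)
        pf = pulse_features(rap, beat_times_from_hr(60, hr))
        assert len(pf.crest_time_ms) == pytest.approx(len(beats), abs=1)


class TestWaveletPowerSpectrum:
    def test_pure_tone_ridge_at_one_hz(self):
        fs = 32.0
        t = np.arange(int(60 * fs)) / fs
        ch = Channel(np.sin(2 * np.pi * 1.0 * t), fs, "au")
        freqs, power = wavelet_power_spectrum(ch, np.geomspace(0.2, 4.0, 40))
        interior = power[:, int(10 * fs) : -int(10 * fs)]
        ridge = freqs[np.argmax(interior, axis=0)]
        assert np.all(np.abs(ridge - 1.0) < 0.15)

    def test_two_tones_two_ridges(self):
        fs = 32.0
        t = np.arange(int(60 * fs)) / fs
        sig = np.sin(2 * np.pi * 1.0 * t) + np.sin(2 * np.pi * 3.0 * t)
        freqs, power = wavelet_power_spectrum(
            Channel(sig, fs, "au"), np.geomspace(0.3, 8.0, 60)
        )
        mean_power = power[:, int(10 * fs) : -int(10 * fs)].mean(axis=1)
        from scipy.signal import find_peaks

        pk, _ = find_peaks(mean_power)
        peak_freqs = sorted(freqs[pk][np.argsort(mean_power[pk])[-2:]])
        assert peak_freqs[0] == pytest.approx(1.0, rel=0.15)
        assert peak_freqs[1] == pytest.approx(3.0, rel=0.15)

    def test_matches_direct_convolution_oracle(self):
        # brute-force oracle: FFT convolution with the sampled Morlet wavelet
        import pywt
        from scipy.signal import fftconvolve

        fs = 16.0
        rng = np.random.default_rng(0)
        sig = rng.normal(size=256)
        freqs = np.array([0.5, 1.0, 2.0])
        _, power = wavelet_power_spectrum(Channel(sig, fs, "au"), freqs)
        wav = pywt.ContinuousWavelet("morl")
        scales = pywt.frequency2scale("morl", freqs / fs)
        for row, scale in zip(power, scales):
            n_psi = max(int(scale * 16), 64)
            psi, x = wav.wavefun(length=n_psi)
            # resample wavelet to the scaled grid, as cwt's integral does
            xi = np.arange(scale * (x[-1] - x[0]) + 1) / (scale * (x[-1] - x[0])) * (x[-1] - x[0]) + x[0]
            psi_s = np.interp(xi, x, psi)
            conv = fftconvolve(sig, psi_s[::-1], mode="same")
            oracle = np.abs(-np.sqrt(scale) * np.diff(np.cumsum(conv) / len(psi_s), prepend=0))
            # compare ridge energy ordering rather than raw samples
            assert np.corrcoef(row, np.abs(conv) ** 2)[0, 1] > 0.8

    def test_frequency_above_nyquist_rejected(self):
        ch = Channel(np.zeros(64), 8.0, "au")
        with pytest.raises(ValueError):
            wavelet_power_spectrum(ch, np.array([5.0]))


class TestMovingAverage:
    def test_constant_series_unchanged(self):
        x = np.full(100, 3.3)
        assert np.allclose(moving_average(x, 30, 1.0), 3.3)

    def test_impulse_plateau_height(self):
        x = np.zeros(101)
        x[50] = 1.0
        out = moving_average(x, 9, 1.0)
        assert out[50] == pytest.approx(1.0 / 9)

    def test_single_sample_window_is_identity(self):
        x = np.arange(20.0)
        assert np.array_equal(moving_average(x, 1, 1.0), x)


class TestCortisolInterpolation:
    def test_exact_at_knots(self):
        ch = SparseChannel([0, 60, 120, 180], [86, 95, 110, 100], "nM")
        out = interpolate_cortisol(ch, np.array([0.0, 60.0, 120.0, 180.0]))
        assert np.allclose(out, [86, 95, 110, 100])

    def test_collinear_points_reproduce_line(self):
        ch = SparseChannel([0, 60, 120], [10, 20, 30], "nM")
        out = interpolate_cortisol(ch, np.array([30.0, 90.0]))
        assert np.allclose(out, [15, 25], atol=1e-9)

    def test_parabola_recovered(self):
        t = np.array([0.0, 30, 60, 90, 120])
        vals = 0.01 * t**2 - 0.5 * t + 90
        ch = SparseChannel(t, vals, "nM")
        tq = np.linspace(0, 120, 41)
        assert np.allclose(interpolate_cortisol(ch, tq), 0.01 * tq**2 - 0.5 * tq + 90, atol=1e-8)

    def test_two_points_fall_back_to_linear_with_warning(self):
        ch = SparseChannel([0, 100], [80, 90], "nM")
        with pytest.warns(UserWarning, match="linear"):
            out = interpolate_cortisol(ch, np.array([50.0]))
        assert out[0] == pytest.approx(85.0)
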