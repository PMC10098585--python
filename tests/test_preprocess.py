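import numpy as np
import pytest

from roma_ppg.errors import ConfigurationError, DataError
from roma_ppg.hr_time import detect_systolic_peaks
from roma_ppg.preprocess import (first_null_hz, highpass_subtract, lowpass,
                                 moving_mean_baseline, normalize_moving_max,
                                 notch_cadence, preprocess)
from roma_ppg.synth import ConstantHR, SynthConfig, generate

FS = 46.3


def tone(freq_hz, fs=FS, duration_s=60.0):
    t = np.arange(int(duration_s * fs)) / fs
    return np.sin(2 * np.pi * freq_hz * t)


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


def db(ratio):
    return 20.0 * np.log10(ratio)


class TestMovingMeanBaseline:
    def test_constant_maps_to_constant(self):
        x = np.full(200, 3.7)
        assert np.allclose(moving_mean_baseline(x, FS), 3.7)

    def test_impulse_response_is_interior_rectangle(self):
        x = np.zeros(200)
        x[100] = 1.0
        y = moving_mean_baseline(x, FS)
        L = round(0.6 * FS)  # centered window [n - (L-1)//2, n + L//2]
        nonzero = np.flatnonzero(y)
        assert nonzero[0] == 100 - L // 2 and nonzero[-1] == 100 + (L - 1) // 2
        assert np.allclose(y[nonzero], 1.0 / L)

    def test_first_spectral_null_kills_sinusoid(self):
        # Dirichlet response sin(pi L f / fs) / (L sin(pi f / fs)) is zero at f = fs/L
        L = 30
        fs = 46.3
        x = tone(fs / L, fs=fs, duration_s=120.0)
        y = moving_mean_baseline(x, fs, window_s=L / fs)
        assert rms(y[200:-200]) < 1e-6 * rms(x)

    def test_linearity(self, rng):
        x, u = rng.normal(size=300), rng.normal(size=300)
        lhs = moving_mean_baseline(2.0 * x + 3.0 * u, FS)
        rhs = 2.0 * moving_mean_baseline(x, FS) + 3.0 * moving_mean_baseline(u, FS)
        assert np.allclose(lhs, rhs)

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            moving_mean_baseline([], FS)


def test_measured_first_null_matches_dirichlet_prediction():
    n = 2 ** 16
    assert first_null_hz(30, 46.3, n) == pytest.approx(46.3 / 30, abs=46.3 / n)


class TestHighpassSubtract:
    def test_constant_input_removed(self):
        x = np.full(300, 5.0)
        v = highpass_subtract(x, moving_mean_baseline(x, FS))
        assert np.allclose(v, 0.0)

    def test_identity_case_exact_zero(self, rng):
        x = rng.normal(size=100)
        assert np.array_equal(highpass_subtract(x, x), np.zeros(100))

    def test_length_mismatch(self):
        with pytest.raises(DataError):
            highpass_subtract(np.ones(3), np.ones(4))

    def test_recovers_pulse_from_slow_drift(self):
        # 1.5 Hz pulse train + 0.2 Hz drift, drift band-limited below fs/(2L)
        t = np.arange(int(120 * FS)) / FS
        s = np.sin(2 * np.pi * 1.5 * t)
        drift = np.sin(2 * np.pi * 0.2 * t)
        v = highpass_subtract(s + drift, moving_mean_baseline(s + drift, FS))
        # compare against the high-passed clean pulse (the filter also shapes s)
        s_ref = highpass_subtract(s, moving_mean_baseline(s, FS))
        err = rms((v - s_ref)[200:-200]) / rms(s_ref[200:-200])
        assert err < 0.05


class TestLowpass:
    def test_dc_and_heart_band_within_half_db(self):
        for f in (0.0, 1.0):
            x = np.ones(int(60 * FS)) if f == 0 else tone(f)
            y = lowpass(x, FS)
            ratio = rms(y[300:-300]) / rms(x[300:-300])
            assert abs(db(ratio)) < 0.5

    def test_stopband_edge_attenuated_60db(self):
        stop = 3.5 + 0.2 * (FS / 2 - 3.5)
        for f in (stop, stop + 3.0):
            y = lowpass(tone(f), FS)
            assert db(rms(y[300:-300]) / rms(tone(f)[300:-300])) <= -60.0

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            lowpass(np.ones(100), fs=6.0, cutoff_hz=3.5)


class TestNotchCadence:
    def test_cadence_tone_suppressed(self):
        y = notch_cadence(tone(100 / 60), FS)
        assert rms(y[300:-300]) <= 0.03 * rms(tone(100 / 60)[300:-300])

    def test_heart_rate_tone_outside_band_preserved(self):
        x = tone(70 / 60)
        y = notch_cadence(x, FS)
        assert abs(db(rms(y[300:-300]) / rms(x[300:-300]))) < 1.0

    def test_zero_input_zero_output(self):
        assert np.allclose(notch_cadence(np.zeros(2000), FS), 0.0)

    def test_band_exceeding_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            notch_cadence(np.ones(100), fs=3.0, center_bpm=100, width_bpm=50)


class TestNormalizeMovingMax:
    def test_scale_invariance(self, rng):
        v = rng.normal(size=400)
        _, r1 = normalize_moving_max(v, FS)
        _, r2 = normalize_moving_max(7.3 * v, FS)
        assert np.allclose(r1, r2)

    def test_adjacent_peaks_both_normalized_to_one(self):
        v = np.zeros(int(2.0 * FS))
        v[int(0.3 * FS)] = 2.0
        v[int(1.3 * FS)] = 4.0
        _, r = normalize_moving_max(v, FS)
        assert r[int(0.3 * FS)] == pytest.approx(1.0)
        assert r[int(1.3 * FS)] == pytest.approx(1.0)

    def test_all_zero_input_returns_zeros(self):
        _, r = normalize_moving_max(np.zeros(100), FS)
        assert np.allclose(r, 0.0)

    def test_normalized_bounded_by_one_where_positive(self, rng):
        v = rng.normal(size=1000)
        w, r = normalize_moving_max(v, FS)
        assert np.all(r[w > 0] <= 1.0 + 1e-9)

    def test_idempotent_on_normalized_pulse_train(self):
        v = np.zeros(int(5 * FS))
        v[np.arange(5) * int(FS) + 10] = 1.0
        _, r = normalize_moving_max(v, FS)
        _, r2 = normalize_moving_max(r, FS)
        assert np.allclose(r2[v > 0], 1.0)


class TestFullChain:
    def test_pulse_timing_preserved_by_zero_phase_chain(self):
        # zero-phase filtering adds no group delay: every systolic peak shifts
        # by the same small constant (from amplitude reshaping), so beat-to-beat
        # timing — the quantity HR is computed from — moves by < 1 sample
        synth = generate(SynthConfig(duration_s=120.0, hr_trajectory=ConstantHR(72.0),
                                     drift_amp=0.0, noise_sd=0.0, hrv_amp=0.0,
                                     hrv_lf_amp=0.0, seed=3))
        rec = synth.record
        proc = preprocess(rec)
        peaks_raw = detect_systolic_peaks(
            (rec.samples - rec.samples.mean()) / np.ptp(rec.samples) * 2, rec.fs, threshold=0.3)
        peaks_proc = detect_systolic_peaks(proc.normalized, rec.fs)
        common = [(a, b) for a in peaks_raw for b in peaks_proc if abs(a - b) < 0.1]
        assert len(common) > 100
        shifts = np.array([b - a for a, b in common])
        assert shifts.max() - shifts.min() <= 1.0 / rec.fs + 1e-9
        assert abs(shifts.mean()) < 4.0 / rec.fs  # constant offset only

    def test_all_sequences_same_length(self, clean70):
        proc = preprocess(clean70.record)
        n = clean70.record.samples.size
        for seq in (proc.baseline, proc.highpassed, proc.lowpassed, proc.moving_max, proc.normalized):
            assert seq.size == n
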