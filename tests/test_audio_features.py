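import numpy as np
import pytest

from _oracles import best_window_oracle, dft_power_oracle
from conftest import make_tone

from callvar.audio_features import (
    compute_spectrogram,
    detect_pulses,
    highpass_filter,
    measure_call,
    measure_recording,
    read_wav,
    rms_envelope,
    segment_calls,
    select_calls,
    write_wav,
)
from callvar.errors import (
    InsufficientDataError,
    InvalidParameterError,
    MeasurementError,
)
from callvar.synthetic_data import CallSpec, synthesize_recording
from callvar.types import CallBounds, CallMeasurement, Recording, SpectrogramConfig

SR = 44100
BIN_HZ = SR / 512


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestHighpass:
    def test_stopband_tone_attenuated(self):
        rec = Recording(make_tone(100.0, 1.0), SR)
        out = highpass_filter(rec, 500.0)
        assert rms(out.samples) < 0.10 * rms(rec.samples)

    def test_passband_tone_preserved(self):
        rec = Recording(make_tone(3000.0, 1.0), SR)
        out = highpass_filter(rec, 500.0)
        assert rms(out.samples) == pytest.approx(rms(rec.samples), rel=0.05)

    def test_zero_in_zero_out(self):
        rec = Recording(np.zeros(SR), SR)
        assert not np.any(highpass_filter(rec, 500.0).samples)

    def test_length_and_rate_preserved(self):
        rec = Recording(make_tone(2000.0, 0.5), SR)
        out = highpass_filter(rec, 500.0)
        assert out.samples.size == rec.samples.size
        assert out.sample_rate == rec.sample_rate

    def test_octave_below_cutoff_attenuation(self):
        # >= 24 dB down one octave below the cutoff
        rec = Recording(make_tone(250.0, 1.0), SR)
        out = highpass_filter(rec, 500.0)
        assert 20 * np.log10(rms(rec.samples) / rms(out.samples)) >= 24.0

    def test_cutoff_at_nyquist_rejected(self):
        rec = Recording(make_tone(1000.0, 0.5), SR)
        with pytest.raises(InvalidParameterError):
            highpass_filter(rec, SR / 2)


class TestSpectrogram:
    def test_bin_centered_sine_peaks_at_bin(self):
        rec = Recording(make_tone(BIN_HZ * 20, 1.0), SR)
        spec = compute_spectrogram(rec)
        assert np.all(np.argmax(spec.power, axis=0) == 20)

    def test_silence_is_zero_power(self):
        rec = Recording(np.zeros(SR), SR)
        assert not np.any(compute_spectrogram(rec).power)

    def test_two_tones_give_two_local_maxima(self):
        x = make_tone(BIN_HZ * 10, 1.0) + make_tone(BIN_HZ * 30, 1.0)
        spec = compute_spectrogram(Recording(x, SR))
        mean = spec.power.mean(axis=1)
        local_max = [k for k in range(1, mean.size - 1)
                     if mean[k] > mean[k - 1] and mean[k] > mean[k + 1]
                     and mean[k] > 0.01 * mean.max()]
        assert local_max == [10, 30]

    def test_matches_direct_dft_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=64)
        config = SpectrogramConfig(window_kind="boxcar", window_samples=64,
                                   overlap_fraction=0.0)
        rec = Recording.__new__(Recording)
        rec.samples, rec.sample_rate, rec.metadata = x, SR, None
        spec = compute_spectrogram(rec, config)
        oracle = dft_power_oracle(list(x))
        np.testing.assert_allclose(spec.power[:, 0], oracle, rtol=1e-8, atol=1e-8)

    def test_axes_and_resolution(self):
        rec = Recording(make_tone(1000.0, 0.5), SR)
        spec = compute_spectrogram(rec)
        assert spec.freqs_hz[1] - spec.freqs_hz[0] == pytest.approx(BIN_HZ)
        assert np.diff(spec.times_s) == pytest.approx(256 / SR)
        assert (spec.power >= 0).all()

    def test_too_short_raises(self):
        rec = Recording(np.zeros(600), SR)
        config = SpectrogramConfig(window_samples=1024, overlap_fraction=0.5)
        with pytest.raises(InsufficientDataError):
            compute_spectrogram(rec, config)

    @pytest.mark.parametrize("overlap", [0.0, 0.75])
    def test_energy_invariant_to_hop(self, overlap):
        rec = Recording(make_tone(2000.0, 2.0), SR)
        base = compute_spectrogram(rec, SpectrogramConfig()).total_energy()
        other = compute_spectrogram(
            rec, SpectrogramConfig(overlap_fraction=overlap)).total_energy()
        assert other == pytest.approx(base, rel=0.01)


class TestSegmentation:
    def test_silence_yields_empty(self):
        rng = np.random.default_rng(0)
        rec = Recording(rng.normal(0, 1e-4, SR), SR)
        assert segment_calls(rec) == []

    def test_two_calls_recovered_with_onset_accuracy(self):
        rec, truth = synthesize_recording([CallSpec(), CallSpec()], [272.0],
                                          noise_floor_db=-40.0, seed=2)
        found = segment_calls(highpass_filter(rec, 500.0))
        assert len(found) == 2
        for got, want in zip(found, truth):
            assert got.onset_s == pytest.approx(want.onset_s, abs=5e-3)
            assert got.offset_s == pytest.approx(want.offset_s, abs=5e-3)

    def test_short_dip_does_not_split(self):
        x = np.concatenate([make_tone(3000.0, 0.1), np.zeros(int(0.010 * SR)),
                            make_tone(3000.0, 0.1)])
        x = np.concatenate([np.zeros(SR // 2), x, np.zeros(SR // 2)])
        rng = np.random.default_rng(3)
        rec = Recording(x + rng.normal(0, 1e-4, x.size), SR)
        assert len(segment_calls(rec, min_gap_ms=50.0)) == 1

    def test_bounds_sorted_nonoverlapping_with_min_gap(self, default_bout):
        recording, _ = default_bout
        bounds = segment_calls(recording)
        for a, b in zip(bounds, bounds[1:]):
            assert a.offset_s < b.onset_s
            assert (b.onset_s - a.offset_s) * 1000 >= 50.0


class TestPulseDetection:
    def test_recovers_exact_pulse_count(self):
        spec = CallSpec(pulse_number=14, pulse_rate_pulses_per_s=64.0,
                        call_duration_ms=(13 / 64.0 + 0.012) * 1000)
        rec, _ = synthesize_recording([spec], [], noise_floor_db=-30.0, seed=4)
        rec = highpass_filter(rec, 500.0)
        call = segment_calls(rec)[0]
        assert len(detect_pulses(rec, call).pulse_onsets_s) == 14

    def test_unmodulated_burst_is_single_pulse(self):
        x = np.concatenate([np.zeros(SR // 2), make_tone(3000.0, 0.1),
                            np.zeros(SR // 2)])
        rng = np.random.default_rng(5)
        rec = Recording(x + rng.normal(0, 1e-4, x.size), SR)
        call = segment_calls(rec)[0]
        assert len(detect_pulses(rec, call).pulse_onsets_s) == 1

    def test_onset_span_accuracy(self):
        # 14 pulses with a 0.203 s first-to-last onset span
        spec = CallSpec(pulse_number=14, pulse_rate_pulses_per_s=13 / 0.203,
                        call_duration_ms=215.1)
        rec, _ = synthesize_recording([spec], [], noise_floor_db=-40.0, seed=6)
        rec = highpass_filter(rec, 500.0)
        call = detect_pulses(rec, segment_calls(rec)[0])
        span = call.pulse_onsets_s[-1] - call.pulse_onsets_s[0]
        assert span == pytest.approx(0.203, abs=3e-3)

    def test_silent_call_raises(self):
        rec = Recording(np.zeros(SR), SR)
        with pytest.raises(MeasurementError):
            detect_pulses(rec, CallBounds(0.1, 0.3))

    def test_bounds_outside_recording_rejected(self):
        rec = Recording(np.zeros(SR), SR)
        with pytest.raises(InvalidParameterError):
            detect_pulses(rec, CallBounds(0.5, 2.0))


class TestMeasureCall:
    def test_pulse_rate_formula(self, default_bout):
        recording, _ = default_bout
        onsets = tuple(0.3 + i * (0.203 / 13) for i in range(14))
        bounds = CallBounds(0.3, 0.52, onsets)
        m = measure_call(recording, bounds)
        assert m.pulse_number == 14
        assert m.pulse_rate_pulses_per_s == pytest.approx(13 / 0.203, rel=1e-9)
        assert m.pulse_rate_pulses_per_s == pytest.approx(64.04, abs=0.01)

    def test_dominant_frequency_within_one_bin(self, default_bout):
        recording, truth = default_bout
        call = detect_pulses(recording, segment_calls(recording)[0])
        m = measure_call(recording, call)
        assert abs(m.dominant_frequency_hz - 3416.0) <= BIN_HZ

    def test_interval_modes(self, default_bout):
        recording, _ = default_bout
        calls = segment_calls(recording)
        first = detect_pulses(recording, calls[0])
        gap = measure_call(recording, first, next_onset_s=calls[1].onset_s)
        period = measure_call(recording, first, next_onset_s=calls[1].onset_s,
                              interval_mode="onset_to_onset")
        assert gap.call_interval_ms == pytest.approx(272.7, abs=10.0)
        assert period.call_interval_ms == pytest.approx(
            gap.call_interval_ms + first.duration_s * 1000, rel=1e-9)
        last = detect_pulses(recording, calls[-1])
        assert measure_call(recording, last).call_interval_ms is None

    def test_bandwidth_of_flat_band_noise(self):
        rng = np.random.default_rng(7)
        n = 10 * SR
        spectrum = np.fft.rfft(rng.normal(size=n))
        freqs = np.fft.rfftfreq(n, 1 / SR)
        spectrum[(freqs < 2000) | (freqs > 4000)] = 0.0
        x = np.fft.irfft(spectrum, n)
        x /= np.abs(x).max()
        onsets = tuple(np.linspace(0.1, 9.5, 20))
        m = measure_call(Recording(x, SR), CallBounds(0.0, 10.0, onsets))
        # 5%..95% energy quantiles of a flat band span 90% of its width
        assert m.bandwidth_hz == pytest.approx(1800.0, abs=BIN_HZ)

    def test_bandwidth_of_pure_tone_is_narrow(self):
        x = make_tone(BIN_HZ * 30, 1.0)
        onsets = (0.1, 0.2, 0.3)
        m = measure_call(Recording(x, SR), CallBounds(0.0, 1.0, onsets))
        assert m.bandwidth_hz <= 3 * BIN_HZ

    def test_amplitude_scale_invariance(self, default_bout):
        recording, _ = default_bout
        call = detect_pulses(recording, segment_calls(recording)[0])
        m1 = measure_call(recording, call)
        scaled = Recording(recording.samples * 0.25, SR)
        m2 = measure_call(scaled, call)
        assert m1.as_dict() == pytest.approx(m2.as_dict())

    def test_too_few_pulses_rejected(self, default_bout):
        recording, _ = default_bout
        with pytest.raises(MeasurementError):
            measure_call(recording, CallBounds(0.3, 0.5, (0.32,)))

    def test_zero_energy_call_rejected(self):
        rec = Recording(np.zeros(SR), SR)
        with pytest.raises(MeasurementError):
            measure_call(rec, CallBounds(0.1, 0.4, (0.15, 0.2)))


class TestSelectCalls:
    @staticmethod
    def _call(snr):
        return CallMeasurement(215.0, 272.0, 3416.0, 2000.0, 14, 64.1, snr_db=snr)

    def test_matches_exhaustive_window_oracle(self):
        snrs = [5.0, 8.0, 30.0, 31.0, 29.0, 30.5, 28.0, 4.0]
        calls = [self._call(s) for s in snrs]
        picked, shortfall = select_calls(calls, k=5)
        start = best_window_oracle(snrs, 5)
        assert not shortfall
        assert picked == calls[start:start + 5]

    def test_exactly_k_is_identity(self):
        calls = [self._call(s) for s in (1.0, 2.0, 3.0, 4.0, 5.0)]
        picked, shortfall = select_calls(calls, k=5)
        assert picked == calls and not shortfall

    def test_shortfall_flagged(self):
        calls = [self._call(s) for s in (1.0, 2.0, 3.0)]
        with pytest.warns(UserWarning):
            picked, shortfall = select_calls(calls, k=5)
        assert picked == calls and shortfall

    def test_empty_input(self):
        with pytest.warns(UserWarning):
            picked, shortfall = select_calls([], k=5)
        assert picked == [] and shortfall


@pytest.mark.parametrize("freq,pulses,rate", [
    (2550.0, 11, 39.2),
    (3416.0, 14, 64.1),
    (4313.0, 18, 79.9),
    (3000.0, 12, 50.0),
])
def test_round_trip_recovery(freq, pulses, rate):
    """Synthesize -> filter -> segment -> detect -> measure recovers the
    ground truth within stated tolerances."""
    duration_ms = ((pulses - 1) / rate + 0.75 / rate) * 1000
    spec = CallSpec(dominant_frequency_hz=freq, pulse_number=pulses,
                    pulse_rate_pulses_per_s=rate, call_duration_ms=duration_ms)
    rec, truth = synthesize_recording([spec], [], noise_floor_db=-30.0, seed=8)
    measurements = measure_recording(highpass_filter(rec, 500.0))
    assert len(measurements) == 1
    m = measurements[0]
    assert m.pulse_number == pulses
    assert abs(m.dominant_frequency_hz - freq) <= BIN_HZ
    assert m.pulse_rate_pulses_per_s == pytest.approx(rate, rel=0.05)
    assert m.call_duration_ms == pytest.approx(duration_ms, abs=10.0)


class TestWavIO:
    def test_round_trip(self, tmp_path):
        rec, _ = synthesize_recording([CallSpec()], [], seed=9)
        path = tmp_path / "call.wav"
        write_wav(path, rec)
        back = read_wav(path)
        assert back.sample_rate == rec.sample_rate
        np.testing.assert_allclose(back.samples, rec.samples, atol=1e-4)

    def test_stereo_collapsed_with_warning(self, tmp_path):
        from scipy.io import wavfile
        rng = np.random.default_rng(1)
        stereo = (rng.normal(0, 0.1, (SR, 2)) * 2 ** 15).astype(np.int16)
        path = tmp_path / "stereo.wav"
        wavfile.write(path, SR, stereo)
        with pytest.warns(UserWarning, match="channel 1"):
            rec = read_wav(path)
        np.testing.assert_allclose(rec.samples, stereo[:, 0] / 2 ** 15)
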