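"""Algorithmic extraction of the six call parameters from mono audio.

Replaces interactive selection with a reproducible chain:
high-pass filter -> RMS-envelope call segmentation -> adaptive-threshold
pulse detection -> spectral measurement over the call.

Spectral settings default to a Hann window of 512 samples with 50%
overlap (hop 256).  Dominant frequency is the peak of the time-averaged
power spectrum over the call; bandwidth is the span between the 5% and
95% cumulative-spectral-energy quantiles, linearly interpolated within
frequency bins.  Pulse rate is (pulse_number - 1) divided by the span
from the first to the last pulse onset.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile
from scipy.ndimage import uniform_filter1d

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    MeasurementError,
)
from .types import (
    PARAMETER_NAMES,
    CallBounds,
    CallMeasurement,
    Recording,
    RecordingMetadata,
    SpectrogramConfig,
)

__all__ = [
    "Spectrogram",
    "highpass_filter",
    "compute_spectrogram",
    "segment_calls",
    "detect_pulses",
    "measure_call",
    "measure_recording",
    "select_calls",
    "read_wav",
    "write_wav",
    "measurements_to_frame",
]

DEFAULT_HIGHPASS_HZ = 500.0


# ---------------------------------------------------------------------------
# filtering and spectrogram
# ---------------------------------------------------------------------------

def highpass_filter(recording: Recording, cutoff_hz: float = DEFAULT_HIGHPASS_HZ,
                    order: int = 4) -> Recording:
    """Zero-phase Butterworth high-pass to suppress low-band noise.

    The default 500 Hz cutoff sits below the lowest call energy of
    interest; zero-phase filtering preserves pulse-onset timing.
    """
    if not 0.0 < cutoff_hz < recording.nyquist_hz:
        raise InvalidParameterError(
            f"cutoff_hz must be in (0, {recording.nyquist_hz}), got {cutoff_hz}"
        )
    sos = signal.butter(order, cutoff_hz, btype="highpass",
                        fs=recording.sample_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, recording.samples)
    return Recording(filtered, recording.sample_rate, recording.metadata)


@dataclass(frozen=True)
class Spectrogram:
    """Time-frequency power matrix with its axes.

    ``power[i, j]`` is |STFT|^2 at frequency ``freqs_hz[i]`` and frame
    centre ``times_s[j]``.
    """

    freqs_hz: np.ndarray
    times_s: np.ndarray
    power: np.ndarray
    config: SpectrogramConfig
    sample_rate: int

    def total_energy(self) -> float:
        """Window-sum-compensated energy; invariant to hop for
        stationary signals."""
        window = signal.get_window(self.config.window_kind,
                                   self.config.window_samples)
        return float(self.power.sum() * self.config.hop_samples
                     / np.sum(window ** 2))

    def mean_spectrum(self) -> np.ndarray:
        return self.power.mean(axis=1)


def compute_spectrogram(recording: Recording,
                        config: SpectrogramConfig | None = None) -> Spectrogram:
    """Magnitude-squared STFT on whole (non-padded) frames.

    Frequency resolution is sample_rate / window_samples; frame step is
    hop_samples / sample_rate.
    """
    config = config or SpectrogramConfig()
    x = recording.samples
    win_n, hop = config.window_samples, config.hop_samples
    if x.size < win_n:
        raise InsufficientDataError(
            f"recording of {x.size} samples shorter than one window ({win_n})"
        )
    window = signal.get_window(config.window_kind, win_n)
    frames = np.lib.stride_tricks.sliding_window_view(x, win_n)[::hop]
    spectra = np.fft.rfft(frames * window, axis=1)
    power = np.abs(spectra.T) ** 2
    freqs = np.fft.rfftfreq(win_n, 1.0 / recording.sample_rate)
    times = (np.arange(frames.shape[0]) * hop + win_n / 2) / recording.sample_rate
    return Spectrogram(freqs, times, power, config, recording.sample_rate)


# ---------------------------------------------------------------------------
# envelope, segmentation, pulse detection
# ---------------------------------------------------------------------------

def rms_envelope(samples: np.ndarray, sample_rate: int,
                 window_ms: float = 2.0) -> np.ndarray:
    """Moving RMS amplitude envelope."""
    size = max(1, round(window_ms * 1e-3 * sample_rate))
    return np.sqrt(uniform_filter1d(np.asarray(samples, float) ** 2, size))


def _noise_floor(envelope: np.ndarray, quantile: float = 0.10) -> float:
    """Mean of the quietest fraction of envelope samples."""
    k = max(1, int(quantile * envelope.size))
    return float(np.mean(np.sort(envelope)[:k]))


def _mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where ``mask`` is True."""
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def segment_calls(recording: Recording, min_gap_ms: float = 50.0,
                  threshold_db_above_noise: float = 10.0,
                  min_duration_ms: float = 20.0,
                  envelope_window_ms: float = 2.0) -> list[CallBounds]:
    """Detect call extents from the smoothed amplitude envelope.

    The detection threshold sits ``threshold_db_above_noise`` dB above a
    noise floor estimated from the quietest 10% of envelope samples.
    Segments separated by less than ``min_gap_ms`` are merged (inter-pulse
    dips do not split a call); segments shorter than ``min_duration_ms``
    are dropped.  Silence yields an empty list.
    """
    sr = recording.sample_rate
    env = rms_envelope(recording.samples, sr, envelope_window_ms)
    peak = float(env.max())
    if peak <= 0.0:
        return []
    floor = _noise_floor(env)
    threshold = max(floor * 10.0 ** (threshold_db_above_noise / 20.0),
                    1e-4 * peak)
    runs = _mask_runs(env > threshold)
    if not runs:
        return []
    # merge runs separated by less than the minimum inter-call gap
    min_gap = round(min_gap_ms * 1e-3 * sr)
    merged: list[list[int]] = [list(runs[0])]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < min_gap:
            merged[-1][1] = stop
        else:
            merged.append([start, stop])
    min_len = round(min_duration_ms * 1e-3 * sr)
    return [CallBounds(start / sr, stop / sr)
            for start, stop in merged if stop - start >= min_len]


def detect_pulses(recording: Recording, bounds: CallBounds,
                  threshold_fraction: float = 0.5,
                  debounce_ms: float = 3.0,
                  envelope_window_ms: float = 1.0,
                  rearm_fraction: float = 0.5) -> CallBounds:
    """Locate pulse onsets inside one call.

    Onsets are upward crossings of the smoothed envelope through an
    adaptive threshold (a fraction of the call's envelope peak), with
    hysteresis: after an onset, the detector re-arms only once the
    envelope falls below ``rearm_fraction`` of the threshold, so jitter
    on a pulse's falling edge cannot register as a new pulse.  Crossings
    closer than ``debounce_ms`` collapse into one pulse.
    """
    sr = recording.sample_rate
    i0 = int(round(bounds.onset_s * sr))
    i1 = int(round(bounds.offset_s * sr))
    if i0 < 0 or i1 > recording.samples.size:
        raise InvalidParameterError("bounds lie outside the recording")
    seg = recording.samples[i0:i1]
    env = rms_envelope(seg, sr, envelope_window_ms)
    peak = float(env.max())
    if peak <= 0.0:
        raise MeasurementError("no envelope peak above threshold (silent call)")
    threshold = threshold_fraction * peak
    rearm_level = rearm_fraction * threshold
    debounce = debounce_ms * 1e-3 * sr
    onsets: list[int] = []
    armed = True
    for idx in np.flatnonzero((env >= threshold) | (env <= rearm_level)):
        if env[idx] >= threshold:
            if armed and (not onsets or idx - onsets[-1] >= debounce):
                onsets.append(int(idx))
            armed = False
        else:
            armed = True
    if not onsets:
        raise MeasurementError("no pulse onset found above threshold")
    onset_times = tuple(bounds.onset_s + i / sr for i in onsets)
    return CallBounds(bounds.onset_s, bounds.offset_s, onset_times)


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------

def _energy_quantile_freq(q: float, cum: np.ndarray, freqs: np.ndarray) -> float:
    """Frequency at cumulative-energy fraction ``q``.

    Each bin's energy is spread uniformly over its width, so the
    crossing is linearly interpolated inside the bin that contains it.
    """
    df = freqs[1] - freqs[0]
    k = int(np.searchsorted(cum, q))
    k = min(k, cum.size - 1)
    prev = cum[k - 1] if k > 0 else 0.0
    frac = (q - prev) / (cum[k] - prev) if cum[k] > prev else 0.5
    return float(freqs[k] - df / 2 + frac * df)


def measure_call(recording: Recording, bounds: CallBounds,
                 next_onset_s: float | None = None,
                 config: SpectrogramConfig | None = None,
                 interval_mode: str = "offset_to_onset",
                 noise_rms: float | None = None) -> CallMeasurement:
    """Measure the six parameters of one call.

    ``bounds`` must carry at least two pulse onsets (pulse rate is
    (n-1)/span and is undefined otherwise).  ``next_onset_s`` is the
    onset of the following call; None marks the last call of a bout,
    whose interval is null.  ``interval_mode`` selects the silent-gap
    ("offset_to_onset", default) or period ("onset_to_onset") reading.
    """
    config = config or SpectrogramConfig()
    if len(bounds.pulse_onsets_s) < 2:
        raise MeasurementError(
            "pulse rate undefined: call has fewer than 2 pulse onsets"
        )
    if interval_mode not in ("offset_to_onset", "onset_to_onset"):
        raise InvalidParameterError(f"unknown interval_mode {interval_mode!r}")

    sr = recording.sample_rate
    i0 = int(round(bounds.onset_s * sr))
    i1 = int(round(bounds.offset_s * sr))
    seg = recording.samples[i0:i1]
    if seg.size < config.window_samples:
        raise InsufficientDataError("call shorter than one analysis window")
    if not np.any(seg):
        raise MeasurementError("degenerate zero-energy call")

    seg_rec = Recording.__new__(Recording)  # skip 512-sample floor re-check
    seg_rec.samples = seg
    seg_rec.sample_rate = sr
    seg_rec.metadata = recording.metadata
    spec = compute_spectrogram(seg_rec, config)
    mean_power = spec.mean_spectrum()
    total = mean_power.sum()
    if total <= 0.0:
        raise MeasurementError("degenerate zero-energy call")

    dominant = float(spec.freqs_hz[int(np.argmax(mean_power))])
    cum = np.cumsum(mean_power) / total
    f5 = _energy_quantile_freq(0.05, cum, spec.freqs_hz)
    f95 = _energy_quantile_freq(0.95, cum, spec.freqs_hz)

    duration_ms = bounds.duration_s * 1000.0
    interval_ms: float | None = None
    if next_onset_s is not None:
        ref = bounds.offset_s if interval_mode == "offset_to_onset" else bounds.onset_s
        interval_ms = (next_onset_s - ref) * 1000.0

    onsets = bounds.pulse_onsets_s
    span = onsets[-1] - onsets[0]
    pulse_rate = (len(onsets) - 1) / span

    snr_db: float | None = None
    if noise_rms is not None and noise_rms > 0.0:
        call_rms = float(np.sqrt(np.mean(seg ** 2)))
        snr_db = 20.0 * np.log10(call_rms / noise_rms)

    return CallMeasurement(
        call_duration_ms=duration_ms,
        call_interval_ms=interval_ms,
        dominant_frequency_hz=dominant,
        bandwidth_hz=f95 - f5,
        pulse_number=len(onsets),
        pulse_rate_pulses_per_s=pulse_rate,
        snr_db=snr_db,
    )


def measure_recording(recording: Recording,
                      config: SpectrogramConfig | None = None,
                      min_gap_ms: float = 50.0,
                      threshold_db_above_noise: float = 10.0,
                      interval_mode: str = "offset_to_onset",
                      ) -> list[CallMeasurement]:
    """Segment, detect pulses, and measure every call of a recording.

    Calls that cannot be measured (too few pulses, too short) are
    skipped with a warning.
    """
    bounds_list = segment_calls(recording, min_gap_ms=min_gap_ms,
                                threshold_db_above_noise=threshold_db_above_noise)
    env = rms_envelope(recording.samples, recording.sample_rate)
    noise_rms = _noise_floor(env)
    measurements: list[CallMeasurement] = []
    for i, bounds in enumerate(bounds_list):
        next_onset = bounds_list[i + 1].onset_s if i + 1 < len(bounds_list) else None
        try:
            with_pulses = detect_pulses(recording, bounds)
            measurements.append(
                measure_call(recording, with_pulses, next_onset, config,
                             interval_mode=interval_mode, noise_rms=noise_rms)
            )
        except (MeasurementError, InsufficientDataError) as exc:
            warnings.warn(f"call {i} at {bounds.onset_s:.3f}s skipped: {exc}")
    return measurements


def select_calls(measurements: list[CallMeasurement], k: int = 5,
                 ) -> tuple[list[CallMeasurement], bool]:
    """Pick the ``k`` consecutive calls maximizing summed SNR.

    Returns ``(selected, shortfall)``; ``shortfall`` is True when fewer
    than ``k`` calls were available (all are returned, with a warning).
    """
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    n = len(measurements)
    if n == 0:
        warnings.warn("no calls to select from")
        return [], True
    if n <= k:
        if n < k:
            warnings.warn(f"only {n} calls available, requested {k}")
        return list(measurements), n < k
    snr = np.array([m.snr_db if m.snr_db is not None else 0.0
                    for m in measurements])
    window_sums = np.convolve(snr, np.ones(k), mode="valid")
    best = int(np.argmax(window_sums))
    return list(measurements[best:best + k]), False


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_PCM_SCALE = {np.dtype("int16"): 2 ** 15, np.dtype("int32"): 2 ** 31,
              np.dtype("uint8"): 2 ** 7}


def read_wav(path: str | Path,
             metadata: RecordingMetadata | None = None) -> Recording:
    """Read a WAV file into a mono float Recording in [-1, 1].

    Stereo files are collapsed to the first channel with a warning.
    """
    sample_rate, data = wavfile.read(str(path))
    if data.ndim == 2:
        warnings.warn(f"{path}: stereo input, using channel 1")
        data = data[:, 0]
    if data.dtype in _PCM_SCALE:
        scale = _PCM_SCALE[data.dtype]
        is_u8 = data.dtype == np.dtype("uint8")
        data = data.astype(np.float64)
        if is_u8:
            data -= 128.0
        data /= scale
    else:
        data = data.astype(np.float64)
    return Recording(data, sample_rate, metadata)


def write_wav(path: str | Path, recording: Recording) -> None:
    """Write a Recording as 16-bit PCM WAV."""
    clipped = np.clip(recording.samples, -1.0, 1.0)
    pcm = np.round(clipped * (2 ** 15 - 1)).astype(np.int16)
    wavfile.write(str(path), recording.sample_rate, pcm)


def measurements_to_frame(individual_id: str,
                          measurements: list[CallMeasurement]) -> pd.DataFrame:
    """One wide row per call: individual_id, call_index, six parameters."""
    rows = []
    for idx, m in enumerate(measurements, start=1):
        row: dict[str, object] = {"individual_id": individual_id,
                                  "call_index": idx}
        row.update(m.as_dict())
        row["snr_db"] = m.snr_db
        rows.append(row)
    cols = ["individual_id", "call_index", *PARAMETER_NAMES, "snr_db"]
    return pd.DataFrame(rows, columns=cols)
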