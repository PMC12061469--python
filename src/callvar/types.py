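"""Domain types shared across the pipeline.

A *call* is one pulsatile vocalization; a *bout* is a train of calls
from one male.  Six parameters are measured per call; the canonical
column order used in every table is :data:`PARAMETER_NAMES`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

#: Canonical measurement columns, in reporting order.
PARAMETER_NAMES: tuple[str, ...] = (
    "call_duration_ms",
    "call_interval_ms",
    "dominant_frequency_hz",
    "bandwidth_hz",
    "pulse_number",
    "pulse_rate_pulses_per_s",
)

#: Human-readable labels for reports.
PARAMETER_LABELS: dict[str, str] = {
    "call_duration_ms": "Call duration (ms)",
    "call_interval_ms": "Call interval (ms)",
    "dominant_frequency_hz": "Dominant frequency (Hz)",
    "bandwidth_hz": "Bandwidth (Hz)",
    "pulse_number": "Pulse number",
    "pulse_rate_pulses_per_s": "Pulse rate (pulses/s)",
}


@dataclass(frozen=True)
class RecordingMetadata:
    """Field metadata attached to one recording (one male)."""

    individual_id: str
    locality: str = ""
    group: str = ""
    temperature_c: float | None = None
    latitude: float | None = None
    longitude: float | None = None
    recording_date: str | None = None

    def __post_init__(self) -> None:
        if self.temperature_c is not None and not math.isfinite(self.temperature_c):
            raise InvalidParameterError("temperature_c must be finite")
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise InvalidParameterError(f"latitude out of range: {self.latitude}")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise InvalidParameterError(f"longitude out of range: {self.longitude}")


@dataclass
class Recording:
    """Mono audio with its sampling rate and optional field metadata.

    Samples are dimensionless amplitudes, nominally in [-1, 1].
    """

    samples: np.ndarray
    sample_rate: int
    metadata: RecordingMetadata | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InvalidParameterError("samples must be one-dimensional (mono)")
        if int(self.sample_rate) <= 0:
            raise InvalidParameterError("sample_rate must be positive")
        self.sample_rate = int(self.sample_rate)
        if self.samples.size < 512:
            raise InvalidParameterError(
                f"recording too short: {self.samples.size} samples (need >= 512)"
            )

    @property
    def nyquist_hz(self) -> float:
        return self.sample_rate / 2.0

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate

    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


@dataclass(frozen=True)
class SpectrogramConfig:
    """Short-time-Fourier settings used for every spectral measurement.

    Defaults: Hann window of 512 samples, 50% overlap, hop of 256 samples.
    """

    window_kind: str = "hann"
    window_samples: int = 512
    overlap_fraction: float = 0.5
    hop_samples: int | None = None

    def __post_init__(self) -> None:
        if self.window_samples < 2:
            raise InvalidParameterError("window_samples must be >= 2")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise InvalidParameterError("overlap_fraction must be in [0, 1)")
        expected_hop = round(self.window_samples * (1.0 - self.overlap_fraction))
        if self.hop_samples is None:
            object.__setattr__(self, "hop_samples", expected_hop)
        elif self.hop_samples != expected_hop:
            raise InvalidParameterError(
                f"hop_samples={self.hop_samples} inconsistent with "
                f"window_samples*(1-overlap)={expected_hop}"
            )

    def frequency_resolution_hz(self, sample_rate: int) -> float:
        return sample_rate / self.window_samples

    def frame_step_s(self, sample_rate: int) -> float:
        return self.hop_samples / sample_rate


@dataclass(frozen=True)
class CallBounds:
    """Temporal extent of one call, optionally with detected pulse onsets.

    All times are seconds from the start of the recording.
    """

    onset_s: float
    offset_s: float
    pulse_onsets_s: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.onset_s < self.offset_s:
            raise InvalidParameterError("onset_s must precede offset_s")
        onsets = tuple(float(t) for t in self.pulse_onsets_s)
        object.__setattr__(self, "pulse_onsets_s", onsets)
        if onsets:
            tol = 1e-9
            if onsets[0] < self.onset_s - tol or onsets[-1] > self.offset_s + tol:
                raise InvalidParameterError("pulse onsets must lie within the call")
            if any(b <= a for a, b in zip(onsets, onsets[1:])):
                raise InvalidParameterError("pulse onsets must be strictly increasing")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class CallMeasurement:
    """The six parameters of one measured call.

    ``call_interval_ms`` is the silent gap to the next call and is None
    for the last call of a bout.  ``snr_db`` is an optional quality score
    used when picking the best consecutive calls.
    """

    call_duration_ms: float
    call_interval_ms: float | None
    dominant_frequency_hz: float
    bandwidth_hz: float
    pulse_number: int
    pulse_rate_pulses_per_s: float
    snr_db: float | None = None

    def __post_init__(self) -> None:
        for name in ("call_duration_ms", "dominant_frequency_hz",
                     "bandwidth_hz", "pulse_rate_pulses_per_s"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise InvalidParameterError(f"{name} must be positive, got {v!r}")
        if self.call_interval_ms is not None and self.call_interval_ms <= 0:
            raise InvalidParameterError("call_interval_ms must be positive or None")
        if self.pulse_number < 2:
            raise InvalidParameterError(
                "pulse_number must be >= 2 when pulse_rate is defined"
            )

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in PARAMETER_NAMES}
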