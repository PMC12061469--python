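"""Ground-truth synthetic inputs: pulsatile call audio and hierarchical
measurement tables.

Audio: each call is a train of raised-cosine-enveloped carrier bursts;
pulse onsets sit at i / pulse_rate, and each pulse lasts
call_duration - onset_span, so the inter-pulse dip depth is controlled
by the duty cycle.

Tables: value(group, locality, individual, call) =
group_mean + locality_effect + individual_effect
+ slope_b * (T_locality - T_ref) + within_call_noise,
with Gaussian effects at configured SDs (log-normal optional for
strictly positive parameters).  True components are returned alongside
so recovery can be scored against configured truth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import study
from .errors import InvalidParameterError
from .types import PARAMETER_NAMES, CallBounds, Recording, RecordingMetadata

__all__ = [
    "CallSpec",
    "synthesize_call",
    "synthesize_recording",
    "LocalityConfig",
    "PopulationConfig",
    "study_population_config",
    "generate_parameter_table",
    "metadata_frame",
]

DEFAULT_SAMPLE_RATE = 44100


@dataclass(frozen=True)
class CallSpec:
    """Ground-truth description of one synthetic call.

    Defaults are the bundled survey's grand means.
    """

    dominant_frequency_hz: float = study.GRAND_MEANS["dominant_frequency_hz"]
    pulse_number: int = 14
    pulse_rate_pulses_per_s: float = study.GRAND_MEANS["pulse_rate_pulses_per_s"]
    call_duration_ms: float = study.GRAND_MEANS["call_duration_ms"]
    pulse_shape: str = "raised_cosine"
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.pulse_number < 1:
            raise InvalidParameterError("pulse_number must be >= 1")
        if not 0.0 < self.amplitude <= 1.0:
            raise InvalidParameterError("amplitude must be in (0, 1]")
        if self.pulse_shape != "raised_cosine":
            raise InvalidParameterError(f"unknown pulse_shape {self.pulse_shape!r}")
        if self.call_duration_ms <= 0:
            raise InvalidParameterError("call_duration_ms must be positive")
        if self.onset_span_s > self.call_duration_ms / 1000.0:
            raise InvalidParameterError(
                "pulse-onset span (pulse_number-1)/pulse_rate exceeds call duration"
            )

    @property
    def onset_span_s(self) -> float:
        if self.pulse_number == 1:
            return 0.0
        return (self.pulse_number - 1) / self.pulse_rate_pulses_per_s

    @property
    def pulse_duration_s(self) -> float:
        """Each pulse fills the tail left after the onset span."""
        return self.call_duration_ms / 1000.0 - self.onset_span_s


def synthesize_call(spec: CallSpec,
                    sample_rate: int = DEFAULT_SAMPLE_RATE,
                    ) -> tuple[np.ndarray, CallBounds]:
    """Render one call; returns (waveform, ground-truth bounds).

    The carrier frequency must sit below Nyquist, and the duty cycle
    must leave a non-degenerate pulse (> 1 ms).
    """
    if spec.dominant_frequency_hz >= sample_rate / 2:
        raise InvalidParameterError("carrier at or above Nyquist")
    pulse_dur = spec.pulse_duration_s
    if pulse_dur <= 1e-3:
        raise InvalidParameterError(
            "onset span leaves no room for a pulse (> 1 ms needed); "
            "increase call_duration_ms"
        )
    duration_s = spec.call_duration_ms / 1000.0
    n = int(math.ceil(duration_s * sample_rate))
    wave = np.zeros(n)
    t = np.arange(n) / sample_rate
    carrier = np.sin(2 * np.pi * spec.dominant_frequency_hz * t)
    pulse_n = max(2, int(round(pulse_dur * sample_rate)))
    envelope = 0.5 * (1.0 - np.cos(2 * np.pi * np.arange(pulse_n) / pulse_n))
    onsets = []
    for i in range(spec.pulse_number):
        onset = 0.0 if spec.pulse_number == 1 else i / spec.pulse_rate_pulses_per_s
        onsets.append(onset)
        j0 = int(round(onset * sample_rate))
        j1 = min(j0 + pulse_n, n)
        wave[j0:j1] += envelope[: j1 - j0] * carrier[j0:j1]
    peak = np.abs(wave).max()
    if peak > 0:
        wave *= spec.amplitude / peak
    return wave, CallBounds(0.0, duration_s, tuple(onsets))


def synthesize_recording(specs, call_intervals_ms,
                         noise_floor_db: float = -60.0,
                         seed: int | None = 0,
                         sample_rate: int = DEFAULT_SAMPLE_RATE,
                         lead_silence_ms: float = 300.0,
                         tail_silence_ms: float = 300.0,
                         metadata: RecordingMetadata | None = None,
                         ) -> tuple[Recording, list[CallBounds]]:
    """Render a bout of calls separated by silent gaps, plus white noise.

    ``call_intervals_ms`` are offset-to-onset gaps (one fewer than
    calls).  ``noise_floor_db`` is the noise RMS in dB relative to the
    unit peak amplitude; -60 dB gives roughly a 60 dB SNR for
    full-amplitude calls.
    """
    specs = list(specs)
    intervals = list(call_intervals_ms)
    if len(intervals) != max(0, len(specs) - 1):
        raise InvalidParameterError(
            f"need {max(0, len(specs) - 1)} intervals for {len(specs)} calls"
        )
    if any(g < 0 for g in intervals):
        raise InvalidParameterError("call intervals must be non-negative")

    rendered = [synthesize_call(s, sample_rate) for s in specs]
    total_s = (lead_silence_ms + tail_silence_ms) / 1000.0
    total_s += sum(b.duration_s for _, b in rendered)
    total_s += sum(intervals) / 1000.0
    n = max(512, int(math.ceil(total_s * sample_rate)))
    samples = np.zeros(n)
    bounds_out: list[CallBounds] = []
    t = lead_silence_ms / 1000.0
    for k, (wave, bounds) in enumerate(rendered):
        j0 = int(round(t * sample_rate))
        samples[j0:j0 + wave.size] += wave
        bounds_out.append(CallBounds(
            t, t + bounds.duration_s,
            tuple(t + o for o in bounds.pulse_onsets_s),
        ))
        t += bounds.duration_s
        if k < len(intervals):
            t += intervals[k] / 1000.0
    rng = np.random.default_rng(seed)
    samples += rng.normal(0.0, 10.0 ** (noise_floor_db / 20.0), n)
    peak = np.abs(samples).max()
    if peak > 1.0:
        samples /= peak
    return Recording(samples, sample_rate, metadata), bounds_out


# ---------------------------------------------------------------------------
# hierarchical measurement tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocalityConfig:
    name: str
    group: str
    latitude: float
    longitude: float
    temperature_c: float
    n_individuals: int


@dataclass
class PopulationConfig:
    """Generator settings for one hierarchical table.

    All effect SDs are on the parameter scale.  ``temp_slopes`` are
    units per degree C applied to the locality temperature offset from
    ``reference_temperature_c`` (None -> count-weighted mean of the
    locality temperatures).
    """

    localities: tuple[LocalityConfig, ...]
    group_means: dict[str, dict[str, float]]
    locality_sd: dict[str, float]
    individual_sd: dict[str, float]
    within_sd: dict[str, float]
    temp_slopes: dict[str, float] = field(default_factory=dict)
    reference_temperature_c: float | None = None
    calls_per_individual: int = 5
    seed: int = 0
    distribution: str = "normal"  # or "lognormal"

    def __post_init__(self) -> None:
        if self.calls_per_individual < 2:
            raise InvalidParameterError("calls_per_individual must be >= 2")
        if self.distribution not in ("normal", "lognormal"):
            raise InvalidParameterError(f"unknown distribution {self.distribution!r}")
        for d in (self.locality_sd, self.individual_sd, self.within_sd):
            if any(v < 0 for v in d.values()):
                raise InvalidParameterError("effect SDs must be non-negative")
        groups = {loc.name: loc.group for loc in self.localities}
        if len(groups) != len(self.localities):
            raise InvalidParameterError("duplicate locality names")

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.group_means.keys())


def study_population_config(seed: int = 0,
                            calls_per_individual: int = 5,
                            individuals_scale: int = 1) -> PopulationConfig:
    """Default configuration mirroring the bundled survey design.

    Nine localities with their published temperatures, coordinates,
    group assignments and male counts; group means from the published
    per-group comparison; effect SDs back-solved from the published CV
    columns (within-individual from mean CV_i, between-individual from
    mean CV_p, locality from the CV_g excess over CV_p) — an
    approximate emulation, not a fit.
    """
    localities = tuple(
        LocalityConfig(s.name, s.group, s.latitude, s.longitude,
                       s.temperature_c, s.n_males * individuals_scale)
        for s in study.STUDY_SITES
    )
    within = {p: study.CV_I_MEAN[p] / 100.0 * study.GRAND_MEANS[p]
              for p in PARAMETER_NAMES}
    individual = {p: study.CV_P_MEAN[p] / 100.0 * study.GRAND_MEANS[p]
                  for p in PARAMETER_NAMES}
    locality = {
        p: math.sqrt(max(study.CV_G_MEAN[p] ** 2 - study.CV_P_MEAN[p] ** 2, 0.0))
        / 100.0 * study.GRAND_MEANS[p]
        for p in PARAMETER_NAMES
    }
    return PopulationConfig(
        localities=localities,
        group_means={p: dict(study.GROUP_MEANS[p]) for p in PARAMETER_NAMES},
        locality_sd=locality,
        individual_sd=individual,
        within_sd=within,
        temp_slopes={p: 0.0 for p in PARAMETER_NAMES},
        reference_temperature_c=None,
        calls_per_individual=calls_per_individual,
        seed=seed,
    )


def metadata_frame(config: PopulationConfig) -> pd.DataFrame:
    """One row per individual: id, locality, group, coordinates,
    temperature."""
    rows = []
    for loc in config.localities:
        for i in range(loc.n_individuals):
            rows.append({
                "individual_id": f"{loc.name}_{i + 1:02d}",
                "locality": loc.name,
                "group": loc.group,
                "latitude": loc.latitude,
                "longitude": loc.longitude,
                "temperature_c": loc.temperature_c,
            })
    return pd.DataFrame(rows)


def generate_parameter_table(config: PopulationConfig,
                             ) -> tuple[pd.DataFrame, dict]:
    """Draw a seeded hierarchical table; returns (long table, truth).

    The truth record holds the drawn locality and individual effects,
    the reference temperature, and the configured components, keyed so
    recovery tests can compare estimates against the generating values.
    """
    rng = np.random.default_rng(config.seed)
    if config.reference_temperature_c is None:
        weights = np.array([loc.n_individuals for loc in config.localities], float)
        temps = np.array([loc.temperature_c for loc in config.localities])
        t_ref = float((weights * temps).sum() / weights.sum())
    else:
        t_ref = config.reference_temperature_c

    truth: dict = {
        "reference_temperature_c": t_ref,
        "locality_effects": {},
        "individual_effects": {},
        "config": config,
    }
    records: list[dict] = []
    for parameter in config.parameters:
        b = config.temp_slopes.get(parameter, 0.0)
        loc_sd = config.locality_sd.get(parameter, 0.0)
        ind_sd = config.individual_sd.get(parameter, 0.0)
        win_sd = config.within_sd.get(parameter, 0.0)
        loc_effects: dict[str, float] = {}
        ind_effects: dict[str, float] = {}
        for loc in config.localities:
            loc_eff = float(rng.normal(0.0, loc_sd)) if loc_sd > 0 else 0.0
            loc_effects[loc.name] = loc_eff
            base = (config.group_means[parameter][loc.group]
                    + loc_eff + b * (loc.temperature_c - t_ref))
            for i in range(loc.n_individuals):
                individual_id = f"{loc.name}_{i + 1:02d}"
                ind_eff = float(rng.normal(0.0, ind_sd)) if ind_sd > 0 else 0.0
                ind_effects[individual_id] = ind_eff
                centre = base + ind_eff
                noise = (rng.normal(0.0, win_sd, config.calls_per_individual)
                         if win_sd > 0 else np.zeros(config.calls_per_individual))
                values = centre + noise
                if config.distribution == "lognormal":
                    # same mean/SD targets via moment-matched log-normal
                    values = _lognormal_like(rng, centre, win_sd,
                                             config.calls_per_individual)
                for c, value in enumerate(values, start=1):
                    records.append({
                        "individual_id": individual_id,
                        "locality": loc.name,
                        "group": loc.group,
                        "parameter": parameter,
                        "call_index": c,
                        "value": float(value),
                    })
        truth["locality_effects"][parameter] = loc_effects
        truth["individual_effects"][parameter] = ind_effects
    table = pd.DataFrame(records, columns=["individual_id", "locality", "group",
                                           "parameter", "call_index", "value"])
    return table, truth


def _lognormal_like(rng: np.random.Generator, mean: float, sd: float,
                    size: int) -> np.ndarray:
    """Log-normal draws moment-matched to (mean, sd); mean must be > 0."""
    if mean <= 0:
        raise InvalidParameterError("lognormal option needs positive means")
    if sd == 0:
        return np.full(size, mean)
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size)
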