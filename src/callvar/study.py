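"""Bundled reference survey: nine sampling sites on Hainan Island.

These constants are the published sampling design and summary statistics
of the source study; they seed the synthetic generator defaults and the
in-repo arithmetic checks (sample accounting, reference temperature,
variability classification).
"""
from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class Site:
    """One sampling locality: coordinates, recording temperature, yield."""

    name: str
    group: str
    longitude: float
    latitude: float
    temperature_c: float
    n_males: int
    recording_date: str


#: The nine survey localities with their geographic group assignment.
STUDY_SITES: tuple[Site, ...] = (
    Site("Haikou City", "NE", 110.25163, 19.98020, 27.9, 3, "2016/5/28"),
    Site("Huiwen Town", "NE", 110.73444, 19.47056, 25.8, 2, "2016/8/11"),
    Site("Chengmai County", "NE", 110.00269, 19.70805, 27.0, 4, "2016/5/29"),
    Site("Lin'gao County", "NE", 109.72374, 19.89148, 26.4, 3, "2016/5/30"),
    Site("Danzhou City", "NE", 109.56134, 19.46854, 27.0, 4, "2016/6/01"),
    Site("Yingjin Village", "NE", 109.28362, 19.71347, 28.9, 5, "2016/5/31"),
    Site("Wuzhishan City", "SW", 109.59653, 18.72689, 26.7, 4, "2016/8/05"),
    Site("Lingshui City", "SW", 110.01676, 18.52668, 28.7, 6, "2016/8/08"),
    Site("Sanya City", "SW", 109.48570, 18.29662, 29.0, 2, "2016/6/09"),
)

#: Published grand means of the six call parameters (over individual means).
GRAND_MEANS: dict[str, float] = {
    "call_duration_ms": 215.1,
    "call_interval_ms": 272.7,
    "dominant_frequency_hz": 3416.0,
    "bandwidth_hz": 2059.0,
    "pulse_number": 14.0,
    "pulse_rate_pulses_per_s": 64.1,
}

#: Published mean within-individual CVs (%), one per parameter.
CV_I_MEAN: dict[str, float] = {
    "call_duration_ms": 3.9,
    "call_interval_ms": 10.4,
    "dominant_frequency_hz": 0.8,
    "bandwidth_hz": 2.8,
    "pulse_number": 4.1,
    "pulse_rate_pulses_per_s": 2.0,
}

#: Published mean within-locality CVs (%) over individual means.
CV_P_MEAN: dict[str, float] = {
    "call_duration_ms": 8.3,
    "call_interval_ms": 14.7,
    "dominant_frequency_hz": 4.3,
    "bandwidth_hz": 20.6,
    "pulse_number": 8.3,
    "pulse_rate_pulses_per_s": 6.0,
}

#: Published mean within-group CVs (%) over individual means.
CV_G_MEAN: dict[str, float] = {
    "call_duration_ms": 12.6,
    "call_interval_ms": 21.5,
    "dominant_frequency_hz": 8.9,
    "bandwidth_hz": 20.2,
    "pulse_number": 11.8,
    "pulse_rate_pulses_per_s": 12.4,
}

#: Published overall CVs (%) over all individual means.
CV_O: dict[str, float] = {
    "call_duration_ms": 17.7,
    "call_interval_ms": 22.5,
    "dominant_frequency_hz": 15.1,
    "bandwidth_hz": 23.9,
    "pulse_number": 12.1,
    "pulse_rate_pulses_per_s": 17.9,
}

#: Published per-group means used as generator defaults.
GROUP_MEANS: dict[str, dict[str, float]] = {
    "call_duration_ms": {"NE": 224.3, "SW": 201.0},
    "call_interval_ms": {"NE": 260.4, "SW": 296.3},
    "dominant_frequency_hz": {"NE": 3190.0, "SW": 3783.0},
    "bandwidth_hz": {"NE": 1908.0, "SW": 2307.0},
    "pulse_number": {"NE": 13.9, "SW": 14.3},
    "pulse_rate_pulses_per_s": {"NE": 60.9, "SW": 69.1},
}

#: Stated reference temperature for the linear temperature correction.
REFERENCE_TEMPERATURE_C: float = 27.6

#: Stated total of recorded males across the nine sites.
TOTAL_RECORDED_MALES: int = 33


def total_recorded_males() -> int:
    """Sum of per-site male counts (sample accounting check)."""
    return sum(site.n_males for site in STUDY_SITES)


def site_temperatures() -> list[float]:
    return [site.temperature_c for site in STUDY_SITES]


def site_male_counts() -> list[int]:
    return [site.n_males for site in STUDY_SITES]
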