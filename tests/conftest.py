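import numpy as np
import pandas as pd
import pytest

from callvar.synthetic_data import CallSpec, synthesize_recording
from callvar.audio_features import highpass_filter


@pytest.fixture
def eight_row_table() -> pd.DataFrame:
    """Hand-made 8-row long table: 2 groups x 1 locality each x
    2 individuals x 2 calls of a single parameter."""
    rows = [
        ("a1", "locA", "G1", "p", 1, 10.0),
        ("a1", "locA", "G1", "p", 2, 12.0),
        ("a2", "locA", "G1", "p", 1, 14.0),
        ("a2", "locA", "G1", "p", 2, 18.0),
        ("b1", "locB", "G2", "p", 1, 20.0),
        ("b1", "locB", "G2", "p", 2, 22.0),
        ("b2", "locB", "G2", "p", 1, 30.0),
        ("b2", "locB", "G2", "p", 2, 26.0),
    ]
    return pd.DataFrame(rows, columns=["individual_id", "locality", "group",
                                       "parameter", "call_index", "value"])


@pytest.fixture
def default_bout():
    """Five default calls with published-mean gaps, filtered, plus truth."""
    rec, truth = synthesize_recording([CallSpec()] * 5, [272.7] * 4,
                                      noise_floor_db=-40.0, seed=1)
    return highpass_filter(rec, 500.0), truth


def make_tone(freq_hz: float, duration_s: float, sample_rate: int = 44100,
              amplitude: float = 1.0) -> np.ndarray:
    t = np.arange(int(duration_s * sample_rate)) / sample_rate
    return amplitude * np.sin(2 * np.pi * freq_hz * t)
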