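import numpy as np
import pytest

from antisaccade.synthetic_cohort import TrialSpec, synthesize_saccade_waveform
from antisaccade.trace_processing import GazeTrace


@pytest.fixture
def trial_spec_right_10():
    return TrialSpec(
        trial_id=0,
        fixation_onset_s=0.0,
        target_onset_s=0.5,
        target_direction=1,
        eccentricity_deg=10,
        target_offset_s=3.0,
    )


def make_trace(x, fs=240.0, y=None):
    x = np.asarray(x, dtype=float)
    t = np.arange(x.size) / fs
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    return GazeTrace(t=t, x=x, y=y)


def padded_saccade_trace(amplitude, duration_ms, vpeak, fs=240.0, pad=60):
    """A single synthetic saccade embedded in a flat trace."""
    w = synthesize_saccade_waveform(amplitude, duration_ms, vpeak, 0.0, fs)
    x = np.concatenate(
        [np.zeros(pad), w.position, np.full(pad, w.position[-1])]
    )
    return make_trace(x, fs), w


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
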