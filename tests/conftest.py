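import numpy as np
import pytest

from csfpulse import FlowWaveform
from csfpulse.templates import WaveformTemplate, default_template


@pytest.fixture(scope="session")
def grid_1s():
    return np.arange(0.0, 1000.0, 10.0)


@pytest.fixture
def sine_waveform(grid_1s):
    """Unit sine over a 1 s cycle, time-normalized (100 samples)."""
    return FlowWaveform(
        times_ms=grid_1s,
        flow=np.sin(2 * np.pi * grid_1s / 1000.0),
        heart_period_ms=1000.0,
        systole_end_ms=430.0,
        compartment="aqueduct",
        time_normalized=True,
    )


@pytest.fixture(scope="session")
def young_arterial_template():
    return default_template("arterial", "young")


@pytest.fixture(scope="session")
def single_harmonic_template():
    """w(t) = sin(2*pi*t/1000): one harmonic, amplitude 1, phase 0."""
    return WaveformTemplate(
        compartment="aqueduct",
        amplitudes=[1.0],
        phases=[0.0],
        systole_ms=430.0,
        baseline=0.0,
        group="young",
    )


def make_waveform(flow, period=1000.0, dt=10.0, normalized=None, **kw):
    t = np.arange(0.0, period - 1e-9, dt)
    flow = np.asarray(flow, dtype=float)
    if flow.size != t.size:
        raise ValueError("flow length mismatch")
    if normalized is None:
        normalized = period == 1000.0 and dt == 10.0
    return FlowWaveform(
        times_ms=t, flow=flow, heart_period_ms=period,
        time_normalized=normalized, **kw,
    )
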