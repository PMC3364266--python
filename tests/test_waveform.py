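"""Waveform metrics, normalization and feature-point detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from csfpulse import (
    FlowWaveform,
    MissingFeatureError,
    average_flow_rate,
    detect_feature_points,
    hermite_fit,
    net_flow_rate,
    normalize_amplitude,
    normalize_time,
    stroke_volume,
)
from csfpulse.synthetic import generate_waveform

from conftest import make_waveform


class TestScalarMetrics:
    def test_average_of_unit_sine_is_two_over_pi(self, sine_waveform):
        # time-average of |sin| over a full cycle is 2/pi mL/s
        expected = 2.0 / np.pi * 60.0
        assert average_flow_rate(sine_waveform) == pytest.approx(expected, rel=1e-3)

    def test_average_of_constant(self):
        w = make_waveform(np.full(100, 5.0))
        assert average_flow_rate(w) == pytest.approx(300.0)
        assert net_flow_rate(w) == pytest.approx(300.0)

    def test_average_of_zero(self):
        w = make_waveform(np.zeros(100))
        assert average_flow_rate(w) == 0.0
        assert stroke_volume(w) == 0.0

    def test_net_flow_of_sine_is_zero(self, sine_waveform):
        assert net_flow_rate(sine_waveform) == pytest.approx(0.0, abs=1e-9)

    def test_net_flow_linearity_with_offset(self, sine_waveform):
        w = sine_waveform.copy(flow=sine_waveform.flow + 0.5)
        assert net_flow_rate(w) == pytest.approx(30.0, abs=1e-6)

    def test_stroke_volume_of_unit_sine(self, sine_waveform):
        # each lobe integrates to T/pi = 318.3 uL
        assert stroke_volume(sine_waveform) == pytest.approx(1000.0 / np.pi, rel=1e-3)

    def test_stroke_volume_unidirectional(self):
        w = make_waveform(np.full(100, 1.0))
        # missing lobe contributes zero area: (1000 + 0)/2
        assert stroke_volume(w) == pytest.approx(500.0)

    def test_empty_waveform_rejected(self):
        with pytest.raises(ValueError):
            FlowWaveform(times_ms=np.array([]), flow=np.array([]), heart_period_ms=1000.0)


class TestNormalizeAmplitude:
    def test_cc_average_yields_unit_average(self, sine_waveform):
        n = normalize_amplitude(sine_waveform, "cc_average")
        assert average_flow_rate(n) / 60.0 == pytest.approx(1.0, abs=1e-12)
        assert n.amplitude_mode == "cc_average"

    def test_systolic_average_divides_by_systolic_mean(self):
        w = make_waveform(np.full(100, 10.0), compartment="arterial")
        w.systole_end_ms = 400.0
        n = normalize_amplitude(w, "systolic_average")
        assert np.allclose(n.flow, 1.0)

    def test_zero_waveform_raises(self):
        w = make_waveform(np.zeros(100))
        with pytest.raises(ZeroDivisionError):
            normalize_amplitude(w, "cc_average")


class TestNormalizeTime:
    def test_constant_short_cycle(self):
        w = make_waveform(np.full(80, 5.0), period=800.0)
        n = normalize_time(w)
        assert n.n_samples == 100
        assert np.allclose(n.flow, 5.0)
        assert np.allclose(n.times_ms, np.arange(0, 1000, 10.0))

    def test_identity_on_normalized_input(self, sine_waveform):
        n = normalize_time(sine_waveform)
        assert np.array_equal(n.flow, sine_waveform.flow)

    def test_idempotence(self):
        rng = np.random.default_rng(0)
        w = make_waveform(rng.normal(size=83), period=830.0)
        n1 = normalize_time(w)
        n2 = normalize_time(n1)
        assert np.array_equal(n1.flow, n2.flow)

    def test_diastolic_extension_is_linear(self):
        # period 800 ms, last value 2, first value 4: the appended tail
        # rises linearly from the end of the native cycle to the first
        # value at t = 1000, so the value at 900 ms is the midpoint 3
        flow = np.linspace(4.0, 2.0, 80)
        w = make_waveform(flow, period=800.0)
        n = normalize_time(w)
        assert n.flow[90] == pytest.approx(3.0)
        assert n.flow[0] == pytest.approx(4.0)

    def test_long_cycle_truncated(self):
        w = make_waveform(np.arange(110.0), period=1100.0)
        n = normalize_time(w)
        assert n.n_samples == 100
        # systolic/early content preserved verbatim
        assert np.allclose(n.flow[:99], np.arange(99.0))


class TestFeaturePoints:
    def test_arterial_template_anchors_recovered(self, young_arterial_template):
        # the template's local extrema are constructed at its anchor nodes
        w = normalize_time(generate_waveform(young_arterial_template, 1000.0))
        feats = detect_feature_points(w, "arterial")
        assert list(feats.points) == ["ar1", "ar2", "ar3", "ar4", "ar5", "ar6"]
        anchor_times = dict(zip(
            ["ar1", "ar2", "ar3", "ar4", "ar5", "ar6"],
            [60, 150, 280, 330, 430, 530],
        ))
        for lbl, (t, _a) in feats.points.items():
            assert abs(t - anchor_times[lbl]) <= 10.0, lbl

    def test_sine_as_aqueductal_flow(self, sine_waveform):
        feats = detect_feature_points(sine_waveform, "aqueduct")
        t_aq1, _ = feats.points["aq1"]
        t_aq2, _ = feats.points["aq2"]
        assert t_aq1 == pytest.approx(250.0, abs=10.0)
        assert t_aq2 == pytest.approx(750.0, abs=10.0)

    def test_monotone_ramp_raises_missing_feature(self):
        w = make_waveform(np.linspace(0, 1, 100), compartment="arterial")
        with pytest.raises(MissingFeatureError) as err:
            detect_feature_points(w, "arterial")
        assert len(err.value.missing) > 0

    def test_requires_time_normalized(self):
        w = make_waveform(np.sin(np.linspace(0, 2 * np.pi, 83, endpoint=False)),
                          period=830.0, normalized=False)
        with pytest.raises(ValueError):
            detect_feature_points(w, "aqueduct")


class TestHermiteFit:
    def test_interpolates_nodes_exactly(self):
        t = np.array([0.0, 100.0, 300.0, 700.0])
        a = np.array([1.0, -2.0, 0.5, 3.0])
        vals = hermite_fit(t, t, amplitudes=a)
        assert np.allclose(vals, a)

    def test_equal_points_give_constant_segment(self):
        vals = hermite_fit(np.array([0.0, 500.0]), np.linspace(0, 500, 51),
                           amplitudes=np.array([2.0, 2.0]))
        assert np.allclose(vals, 2.0)

    def test_monotone_data_monotone_interpolant(self):
        t = np.array([0.0, 100.0, 400.0, 900.0])
        a = np.array([0.0, 1.0, 1.5, 4.0])
        dense = np.linspace(0, 900, 901)
        vals = hermite_fit(t, dense, amplitudes=a)
        assert np.all(np.diff(vals) >= -1e-12)
        assert vals.min() == pytest.approx(0.0)

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError):
            hermite_fit(np.array([0.0, 0.0, 10.0]), [5.0], amplitudes=np.array([1, 2, 3.0]))


@settings(max_examples=40, deadline=None)
@given(st.lists(st.floats(-50, 50), min_size=10, max_size=100),
       st.integers(0, 1000))
def test_average_dominates_net_flow(values, _seed):
    w = make_waveform(np.asarray(values, dtype=float),
                      period=10.0 * len(values), dt=10.0, normalized=False)
    assert average_flow_rate(w) >= abs(net_flow_rate(w)) - 1e-9


@settings(max_examples=40, deadline=None)
@given(st.lists(st.floats(-50, 50), min_size=10, max_size=100))
def test_stroke_volume_sign_flip_invariant(values):
    w = make_waveform(np.asarray(values, dtype=float),
                      period=10.0 * len(values), dt=10.0, normalized=False)
    flipped = w.copy(flow=-w.flow)
    assert stroke_volume(w) == pytest.approx(stroke_volume(flipped), rel=1e-12, abs=1e-12)
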