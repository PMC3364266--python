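"""Flow-waveform container and scalar/normalization/feature operations.

A :class:`FlowWaveform` holds one composite (retrospectively gated) cardiac
cycle of volumetric flow. CSF waveforms use the cranial-positive sign
convention (positive = flow toward the head); arterial waveforms are
positive for inflow. Scalar metrics (cycle-average of |Q|, net flow, stroke
volume) are computed on the subject's native cycle; amplitude normalization
divides by the cycle average (CSF) or the systolic-phase average (arterial);
temporal normalization maps every cycle onto a nominal 1 s cycle sampled at
10 ms by extending or truncating diastole while leaving systole untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "FlowWaveform",
    "FeaturePointSet",
    "ScalarMetrics",
    "MissingFeatureError",
    "average_flow_rate",
    "net_flow_rate",
    "stroke_volume",
    "scalar_metrics",
    "normalize_amplitude",
    "normalize_time",
    "detect_feature_points",
    "hermite_fit",
]

NOMINAL_CYCLE_MS = 1000.0
RESAMPLE_DT_MS = 10.0

#: Feature-point labels per compartment, in required temporal order.
FEATURE_LABELS = {
    "arterial": ["ar1", "ar2", "ar3", "ar4", "ar5", "ar6"],
    "spinal": ["sp1", "sp2", "sp3", "sp4", "sp5", "sp6"],
    "aqueduct": ["aq1", "aq2", "aq3", "aq4", "aq5"],
}


class MissingFeatureError(ValueError):
    """A required waveform feature point could not be located."""

    def __init__(self, compartment: str, missing: list[str]):
        self.compartment = compartment
        self.missing = list(missing)
        super().__init__(
            f"missing feature point(s) for {compartment!r}: {', '.join(missing)}"
        )


@dataclass
class FlowWaveform:
    """One cardiac cycle of volumetric flow.

    Parameters
    ----------
    times_ms : array
        Sample times in ms from the R-wave, strictly increasing, in
        ``[0, heart_period_ms)``.
    flow : array
        Flow in mL/s (dimensionless once amplitude-normalized).
    heart_period_ms : float
        Length of the cardiac cycle.
    systole_end_ms : float, optional
        End of the systolic phase (for arterial waveforms, the minimum at
        aortic valve closure).
    """

    times_ms: np.ndarray
    flow: np.ndarray
    heart_period_ms: float
    systole_end_ms: float | None = None
    compartment: str = ""
    cranial_positive: bool = True
    amplitude_mode: str = "none"  # none | cc_average | systolic_average
    time_normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if self.times_ms.ndim != 1 or self.times_ms.shape != self.flow.shape:
            raise ValueError("times and flow must be 1-D arrays of equal length")
        if self.times_ms.size == 0:
            raise ValueError("empty waveform")
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.times_ms[0] < 0 or self.times_ms[-1] >= self.heart_period_ms:
            raise ValueError("sample times must lie within [0, heart period)")
        if not np.all(np.isfinite(self.flow)):
            raise ValueError("flow values must be finite")
        if self.amplitude_mode not in ("none", "cc_average", "systolic_average"):
            raise ValueError(f"unknown amplitude mode {self.amplitude_mode!r}")

    @property
    def n_samples(self) -> int:
        return self.times_ms.size

    def copy(self, **changes) -> "FlowWaveform":
        out = replace(self, **changes)
        out.meta = dict(self.meta, **changes.get("meta", {}))
        return out

    def sample_periodic(self, t_ms) -> np.ndarray:
        """Linear interpolation treating the waveform as periodic."""
        t = np.asarray(t_ms, dtype=float) % self.heart_period_ms
        tt = np.concatenate([self.times_ms, [self.times_ms[0] + self.heart_period_ms]])
        ff = np.concatenate([self.flow, [self.flow[0]]])
        return np.interp(t, tt, ff)


@dataclass
class FeaturePointSet:
    """Labeled waveform feature points (times in ms, amplitudes in the
    waveform's units)."""

    compartment: str
    points: dict  # label -> (time_ms, amplitude)

    def __post_init__(self):
        labels = list(self.points)
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate feature labels")

    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.points.values()])

    def amplitudes(self) -> np.ndarray:
        return np.array([a for _, a in self.points.values()])


@dataclass
class ScalarMetrics:
    average_flow_ml_min: float
    net_flow_ml_min: float
    stroke_volume_ul: float


def _cycle_integral(w: FlowWaveform, values: np.ndarray) -> float:
    """Trapezoidal integral of `values` over one full cycle (ms units),
    closing the cycle periodically from the last sample back to the first."""
    t = np.concatenate([w.times_ms, [w.times_ms[0] + w.heart_period_ms]])
    v = np.concatenate([values, [values[0]]])
    return float(np.trapezoid(v, t))


def average_flow_rate(w: FlowWaveform) -> float:
    """Cycle average of |Q| in mL/min (the clinical 'average flow rate').

    The time-average of the absolute flow over one cardiac cycle, i.e. the
    mean of the caudocranial and craniocaudal flow magnitudes. Not the net
    flow (see :func:`net_flow_rate`).
    """
    return _cycle_integral(w, np.abs(w.flow)) / w.heart_period_ms * 60.0


def net_flow_rate(w: FlowWaveform) -> float:
    """Signed cycle average of Q in mL/min (net flow, e.g. CSF production)."""
    return _cycle_integral(w, w.flow) / w.heart_period_ms * 60.0


def stroke_volume(w: FlowWaveform) -> float:
    """Mean of the absolute areas under the two flow directions, in µL.

    Defined as the mean of the absolute values of the areas under the
    volumetric flow curve in the two flow directions (systolic and diastolic
    lobes). A missing lobe contributes area 0.
    """
    pos = _cycle_integral(w, np.clip(w.flow, 0.0, None))  # mL/s * ms = µL
    neg = -_cycle_integral(w, np.clip(w.flow, None, 0.0))
    return 0.5 * (abs(pos) + abs(neg))


def scalar_metrics(w: FlowWaveform) -> ScalarMetrics:
    return ScalarMetrics(
        average_flow_ml_min=average_flow_rate(w),
        net_flow_ml_min=net_flow_rate(w),
        stroke_volume_ul=stroke_volume(w),
    )


def _systolic_mask(w: FlowWaveform) -> np.ndarray:
    if w.systole_end_ms is None:
        raise ValueError("waveform has no systole end marker")
    return w.times_ms <= w.systole_end_ms


def normalize_amplitude(w: FlowWaveform, mode: str) -> FlowWaveform:
    """Divide the waveform by its cycle-average |Q| (``cc_average``, CSF) or
    by the systolic-phase average |Q| (``systolic_average``, arterial)."""
    if mode == "cc_average":
        denom = average_flow_rate(w) / 60.0  # mL/s
    elif mode == "systolic_average":
        m = _systolic_mask(w)
        denom = float(np.mean(np.abs(w.flow[m])))
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if denom <= 0 or not np.isfinite(denom):
        raise ZeroDivisionError("zero average flow: amplitude normalization undefined")
    out = w.copy(flow=w.flow / denom, amplitude_mode=mode)
    out.meta["amplitude_norm_factor_ml_s"] = denom
    return out


def normalize_time(
    w: FlowWaveform,
    nominal_ms: float = NOMINAL_CYCLE_MS,
    dt_ms: float = RESAMPLE_DT_MS,
) -> FlowWaveform:
    """Map the cycle onto a nominal length (default 1 s) at a fixed sampling
    interval (default 10 ms), preserving the timing of systole.

    Short cycles are extended by a linear diastolic tail from the last data
    point back to the value of the first point at t = nominal; long cycles
    have their end-diastolic content beyond the nominal length dropped.
    The result is resampled by linear interpolation onto 0, dt, ..,
    nominal - dt, treating the cycle as periodic with the nominal period.
    """
    T = w.heart_period_ms
    if w.systole_end_ms is not None and T < w.systole_end_ms:
        raise ValueError("heart period shorter than systole")
    t, v = w.times_ms, w.flow
    if T < nominal_ms:
        # Hold the last value to the end of the native cycle, then rise/fall
        # linearly to the first sample's value at t = nominal.
        t = np.concatenate([t, [T, nominal_ms]])
        v = np.concatenate([v, [v[-1], v[0]]])
    else:
        keep = t < nominal_ms
        t = np.concatenate([t[keep], [nominal_ms]])
        v = np.concatenate([v[keep], [v[0]]])
    grid = np.arange(0.0, nominal_ms, dt_ms)
    out_v = np.interp(grid, t, v)
    out = w.copy(
        times_ms=grid,
        flow=out_v,
        heart_period_ms=nominal_ms,
        time_normalized=True,
    )
    out.meta["native_period_ms"] = T
    return out


def _smooth3(v: np.ndarray) -> np.ndarray:
    """Circular 3-point moving average (minimal smoothing before feature
    detection)."""
    return (np.roll(v, 1) + v + np.roll(v, -1)) / 3.0


def _local_extrema(t, v):
    """Indices of local maxima and minima of v (circular first difference)."""
    d = np.diff(v)
    maxima, minima = [], []
    for i in range(1, len(v) - 1):
        if d[i - 1] > 0 and d[i] <= 0:
            maxima.append(i)
        elif d[i - 1] < 0 and d[i] >= 0:
            minima.append(i)
    return maxima, minima


def _inflections(v):
    """Indices where the circular second difference changes sign."""
    d2 = np.roll(v, -1) - 2 * v + np.roll(v, 1)
    idx = []
    for i in range(len(v)):
        a, b = d2[i - 1], d2[i]
        if a == 0:
            continue
        if np.sign(a) != np.sign(b) and b != 0:
            idx.append(i)
    return idx


def _first(seq, pred):
    for x in seq:
        if pred(x):
            return x
    return None


def detect_feature_points(w: FlowWaveform, compartment: str | None = None) -> FeaturePointSet:
    """Locate the labeled feature points of a time-normalized waveform.

    Extrema are sign changes of the first difference and inflection points
    sign changes of the second difference, both on a lightly smoothed copy;
    amplitudes are read from the unsmoothed waveform. Labels follow the
    compartment's canonical temporal ordering:

    - arterial ar1..ar6: diastolic minimum, systolic maximum, late systolic
      local minimum, late systolic peak, minimum at aortic valve closure,
      diastolic maximum (all required);
    - spinal sp1..sp6: local maximum of cranial flow, maximum caudal flow,
      inflection point, local maximum, local minimum, maximum cranial flow;
    - aqueduct aq1..aq5: maximum cranial flow, maximum caudal flow, then the
      first/second/third inflection points (inflections optional: a smooth
      near-sinusoidal cycle has only two).
    """
    if not w.time_normalized:
        raise ValueError("feature detection requires a time-normalized waveform")
    comp = compartment or w.compartment
    if comp not in FEATURE_LABELS:
        raise ValueError(f"unknown compartment {comp!r}")
    t, raw = w.times_ms, w.flow
    v = _smooth3(raw)
    maxima, minima = _local_extrema(t, v)
    points: dict[str, tuple[float, float]] = {}

    def put(label, i):
        if i is not None:
            points[label] = (float(t[i]), float(raw[i]))

    if comp == "arterial":
        if maxima:
            ar2 = int(maxima[np.argmax(v[maxima])])
            put("ar2", ar2)
            put("ar1", max((i for i in minima if i < ar2), default=None))
            ar3 = _first(minima, lambda i: i > ar2)
            put("ar3", ar3)
            if ar3 is not None:
                ar4 = _first(maxima, lambda i: i > ar3)
                put("ar4", ar4)
                if ar4 is not None:
                    ar5 = _first(minima, lambda i: i > ar4)
                    put("ar5", ar5)
                    if ar5 is not None:
                        later_max = [i for i in maxima if i > ar5]
                        if later_max:
                            put("ar6", later_max[int(np.argmax(v[later_max]))])
        required = FEATURE_LABELS["arterial"]
    elif comp == "spinal":
        if minima:
            sp2 = int(minima[np.argmin(v[minima])])
            put("sp2", sp2)
            early_max = [i for i in maxima if i < sp2]
            if early_max:
                put("sp1", early_max[int(np.argmax(v[early_max]))])
            sp4 = _first(maxima, lambda i: i > sp2)
            infl = _inflections(v)
            if sp4 is not None:
                put("sp4", sp4)
                put("sp3", _first(infl, lambda i: sp2 < i < sp4))
                sp5 = _first(minima, lambda i: i > sp4)
                put("sp5", sp5)
                if sp5 is not None:
                    later_max = [i for i in maxima if i > sp5]
                    if later_max:
                        put("sp6", later_max[int(np.argmax(v[later_max]))])
        required = ["sp1", "sp2", "sp3", "sp4", "sp5", "sp6"]
    else:  # aqueduct
        if maxima and minima:
            put("aq1", int(maxima[int(np.argmax(v[maxima]))]))
            put("aq2", int(minima[int(np.argmin(v[minima]))]))
            for lbl, i in zip(("aq3", "aq4", "aq5"), _inflections(v)):
                put(lbl, i)
        required = ["aq1", "aq2"]

    missing = [lbl for lbl in required if lbl not in points]
    if missing:
        raise MissingFeatureError(comp, missing)
    ordered = {lbl: points[lbl] for lbl in FEATURE_LABELS[comp] if lbl in points}
    return FeaturePointSet(compartment=comp, points=ordered)


def hermite_fit(points: FeaturePointSet | np.ndarray, grid, amplitudes=None) -> np.ndarray:
    """Shape-preserving piecewise cubic Hermite (PCHIP) interpolation of
    feature points, evaluated on ``grid``.

    Accepts either a :class:`FeaturePointSet` or explicit time/amplitude
    arrays. Interpolates every node exactly and does not overshoot beyond
    adjacent node values on monotone segments.
    """
    if isinstance(points, FeaturePointSet):
        t, a = points.times(), points.amplitudes()
        order = np.argsort(t)
        t, a = t[order], a[order]
    else:
        t = np.asarray(points, dtype=float)
        a = np.asarray(amplitudes, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("duplicate or non-increasing node times")
    return PchipInterpolator(t, a)(np.asarray(grid, dtype=float))
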