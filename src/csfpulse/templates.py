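"""Packaged waveform templates and group calibration constants.

The templates parameterize group-specific (young / elderly) characteristic
waveforms of cerebral arterial inflow, cervical spinal CSF flow (C3-C4) and
aqueductal CSF flow as the first K harmonics of a nominal 1 s cycle. They
are synthetic: anchor-point morphologies chosen to reproduce the
qualitative features of the measured group-mean waveforms (sharp systolic
arterial peak with dicrotic structure, biphasic caudal-dominant CSF pulses,
smoother and more sinusoidal shapes in the elderly, more high-harmonic
energy in the young), not digitized measurements.

Group calibration constants (arterial-to-CSF lags and transfer crossover
frequencies) are the packaged study values, so that end-to-end runs of the
pipeline are construction-parameter recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "WaveformTemplate",
    "CouplingSpec",
    "CohortSpec",
    "default_template",
    "default_coupling",
    "default_cohort_spec",
    "PHYSICAL_SCALE_ML_S",
]

NOMINAL_MS = 1000.0

#: Dimensionless template units -> mL/s, per compartment. Chosen so cohort
#: metrics land in the physiological range (total arterial inflow of a few
#: hundred mL/min; aqueductal stroke volumes of tens of µL).
PHYSICAL_SCALE_ML_S = {"arterial": 11.0, "spinal": 1.5, "aqueduct": 0.11}

#: Default waveform-level measurement noise SD per compartment (mL/s),
#: about 1% of each compartment's typical pulsatile (mean-removed) flow SD
#: as generated by the coupling model: composite cycles from retrospective
#: gating average hundreds of beats, so the residual noise on the gated
#: flow curve is far below single-image noise.
DEFAULT_NOISE_SD_ML_S = {"arterial": 0.06, "spinal": 0.0005, "aqueduct": 0.00005}


@dataclass
class WaveformTemplate:
    """Harmonic parameterization of one compartment's characteristic cycle.

    The nominal-cycle waveform is
    ``w(t) = baseline + sum_k amp[k] * sin(2*pi*(k+1)*t/1000 + phase[k])``.
    """

    compartment: str  # arterial | spinal | aqueduct
    amplitudes: np.ndarray
    phases: np.ndarray
    systole_ms: float
    baseline: float = 0.0
    group: str = ""
    sex: str | None = None
    anchors: tuple = field(default=(), repr=False)  # (t_ms, value) morphology nodes

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        if self.amplitudes.size < 1:
            raise ValueError("template needs at least one harmonic")
        if self.amplitudes.shape != self.phases.shape:
            raise ValueError("amplitudes and phases must have equal length")
        if np.any(~np.isfinite(self.amplitudes)) or np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be finite and nonnegative")
        if not 0 < self.systole_ms < NOMINAL_MS:
            raise ValueError("systole duration must lie inside the nominal cycle")

    @property
    def n_harmonics(self) -> int:
        return self.amplitudes.size

    def evaluate(self, t_ms) -> np.ndarray:
        """Nominal-cycle waveform at the given times (ms)."""
        t = np.asarray(t_ms, dtype=float)
        k = np.arange(1, self.n_harmonics + 1)
        arg = 2.0 * np.pi * np.outer(t, k) / NOMINAL_MS + self.phases
        return self.baseline + np.sin(arg) @ self.amplitudes


@dataclass
class CouplingSpec:
    """Arterial-to-CSF coupling parameters for one group."""

    spinal_lag_ms: float
    aqueduct_lag_ms: float
    spinal_crossover_hz: float
    aqueduct_crossover_hz: float
    #: total order of the coupling system (2 low-pass poles, the rest
    #: all-pass delay sections)
    filter_order: int = 5
    group: str = ""

    def __post_init__(self):
        for lag in (self.spinal_lag_ms, self.aqueduct_lag_ms):
            if not 0 <= lag < NOMINAL_MS:
                raise ValueError("lags must lie in [0, cycle length)")
        if self.spinal_crossover_hz <= 0 or self.aqueduct_crossover_hz <= 0:
            raise ValueError("crossover frequencies must be positive")
        if self.filter_order < 3:
            raise ValueError("filter order must be >= 3 (low-pass + delay sections)")

    def lag_ms(self, compartment: str) -> float:
        return {"spinal": self.spinal_lag_ms, "aqueduct": self.aqueduct_lag_ms}[compartment]

    def crossover_hz(self, compartment: str) -> float:
        return {
            "spinal": self.spinal_crossover_hz,
            "aqueduct": self.aqueduct_crossover_hz,
        }[compartment]


@dataclass
class CohortSpec:
    """Synthetic cohort description."""

    n_subjects: int = 11
    heart_period_mean_ms: float = 831.0
    heart_period_sd_ms: float = 169.0
    heart_period_range_ms: tuple = (500.0, 1200.0)
    noise_sd_ml_s: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD_ML_S))
    seed: int = 0
    group: str = ""

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("need at least one subject")
        lo, hi = self.heart_period_range_ms
        if not 500.0 <= lo < hi <= 1200.0:
            raise ValueError("heart periods must be sampled within [500, 1200] ms")


# --- packaged group morphologies -------------------------------------------
# Anchor nodes (t_ms, value) of the characteristic cycles; PCHIP through the
# anchors (periodically closed) defines the shape, whose leading harmonics
# become the template. The young shapes carry sharper transients and hence
# more high-harmonic energy than the elderly ones.

_ANCHORS = {
    ("arterial", "young"): (
        (0, 0.75), (60, 0.65), (150, 2.90), (280, 1.45), (330, 1.75),
        (430, 0.95), (530, 1.25), (700, 0.95), (860, 0.82),
    ),
    ("arterial", "elderly"): (
        (0, 0.80), (70, 0.70), (160, 2.35), (290, 1.55), (350, 2.05),
        (460, 1.05), (580, 1.18), (750, 0.95), (880, 0.86),
    ),
    ("spinal", "young"): (
        (0, 0.10), (60, 0.50), (190, -1.55), (380, 0.25), (480, 0.05),
        (620, 0.55), (820, 0.25),
    ),
    ("spinal", "elderly"): (
        (0, 0.10), (80, 0.40), (210, -1.30), (420, 0.20), (520, 0.08),
        (660, 0.45), (840, 0.20),
    ),
    ("aqueduct", "young"): (
        (0, 0.50), (80, 1.00), (280, -1.60), (520, 0.15), (700, 0.45),
        (870, 0.60),
    ),
    ("aqueduct", "elderly"): (
        (0, 0.40), (100, 0.90), (320, -1.30), (600, 0.20), (800, 0.55),
    ),
}

_N_HARMONICS = {
    ("arterial", "young"): 12,
    ("arterial", "elderly"): 8,
    ("spinal", "young"): 8,
    ("spinal", "elderly"): 6,
    ("aqueduct", "young"): 6,
    ("aqueduct", "elderly"): 4,
}

_SYSTOLE_MS = {"young": 430.0, "elderly": 460.0}


def _harmonics_from_anchors(anchors, n_harmonics):
    """Leading single-sided harmonics of the periodic PCHIP through anchors."""
    t = np.array([a[0] for a in anchors], dtype=float)
    v = np.array([a[1] for a in anchors], dtype=float)
    t = np.concatenate([t, [NOMINAL_MS]])
    v = np.concatenate([v, [v[0]]])
    dense = np.arange(0.0, NOMINAL_MS, 5.0)
    curve = PchipInterpolator(t, v)(dense)
    n = dense.size
    X = np.fft.rfft(curve)
    baseline = float(X[0].real / n)
    amps = 2.0 * np.abs(X[1 : n_harmonics + 1]) / n
    # w uses sin(arg + phase); rfft coefficient a*e^{j*angle} corresponds to
    # amplitude*cos(wt + angle) = amplitude*sin(wt + angle + pi/2)
    phases = np.angle(X[1 : n_harmonics + 1]) + np.pi / 2.0
    return baseline, amps, phases


def default_template(compartment: str, group: str) -> WaveformTemplate:
    """Packaged characteristic-waveform template for a compartment/group."""
    key = (compartment, group)
    if key not in _ANCHORS:
        raise KeyError(f"no packaged template for {key}")
    anchors = _ANCHORS[key]
    baseline, amps, phases = _harmonics_from_anchors(anchors, _N_HARMONICS[key])
    return WaveformTemplate(
        compartment=compartment,
        amplitudes=amps,
        phases=phases,
        systole_ms=_SYSTOLE_MS[group],
        baseline=baseline,
        group=group,
        anchors=anchors,
    )


#: Packaged group calibration: cross-correlation lags (ms) and transfer
#: crossover frequencies (Hz) used as construction parameters.
_COUPLING = {
    "young": dict(
        spinal_lag_ms=55.0, aqueduct_lag_ms=160.0,
        spinal_crossover_hz=0.5, aqueduct_crossover_hz=0.8,
    ),
    "elderly": dict(
        spinal_lag_ms=34.0, aqueduct_lag_ms=132.0,
        spinal_crossover_hz=3.0, aqueduct_crossover_hz=0.5,
    ),
}


def default_coupling(group: str) -> CouplingSpec:
    """Packaged CouplingSpec for a group (lags and crossovers)."""
    return CouplingSpec(group=group, **_COUPLING[group])


def default_cohort_spec(group: str, seed: int = 0) -> CohortSpec:
    return CohortSpec(group=group, seed=seed)
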