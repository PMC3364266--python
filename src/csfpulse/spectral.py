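"""Harmonic decomposition of normalized waveforms and noise-threshold
calibration.

After temporal normalization every cycle is exactly 1 s long and sampled at
10 ms, so the DFT bins fall on integer frequencies (1 Hz, 2 Hz, ...) for all
subjects, which is what makes group-level comparison of frequency components
possible. The zero-frequency bin is excluded: after amplitude normalization
it no longer corresponds to net flow.

The noise-threshold calibration reproduces the study's rule: one-fifth of
each subject's background-noise SD per compartment, maximized over subjects,
is the magnitude below which a frequency component is considered
indistinguishable from noise. The one-fifth factor itself is reproducible
with :func:`detectability_simulation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .waveform import FlowWaveform

__all__ = [
    "Spectrum",
    "NoiseCalibration",
    "COMPONENT_COUNTS",
    "dft_components",
    "calibrate_noise_threshold",
    "detectability_simulation",
]

#: Number of reported frequency components per compartment.
COMPONENT_COUNTS = {"arterial": 10, "spinal": 7, "aqueduct": 5}


@dataclass
class Spectrum:
    """Single-sided harmonic amplitudes of a normalized flow waveform."""

    frequencies_hz: np.ndarray  # integer frequencies 1..K
    magnitudes: np.ndarray
    compartment: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frequencies_hz = np.asarray(self.frequencies_hz)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if np.any(self.frequencies_hz < 1):
            raise ValueError("zero frequency is excluded from the spectrum")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be nonnegative")


@dataclass
class NoiseCalibration:
    """Per-compartment frequency thresholds from background-noise SDs."""

    thresholds: dict  # compartment -> max over subjects of SD/5
    per_subject_sds: dict  # compartment -> list of SDs

    def negligible(self, spectrum: Spectrum) -> np.ndarray:
        """Boolean flags: magnitude below the compartment threshold."""
        thr = self.thresholds[spectrum.compartment]
        return spectrum.magnitudes < thr


def dft_components(w: FlowWaveform, k_max: int | None = None) -> Spectrum:
    """Single-sided harmonic amplitudes 2|X_k|/N for k = 1..k_max.

    Requires a time-normalized waveform (100 samples over 1 s) so that bin k
    corresponds to exactly k Hz. The scaling makes a unit-amplitude sine at
    an integer frequency report magnitude 1.
    """
    if not w.time_normalized:
        raise ValueError("dft_components requires a time-normalized waveform")
    n = w.n_samples
    if k_max is None:
        k_max = COMPONENT_COUNTS.get(w.compartment, n // 2 - 1)
    if not 1 <= k_max <= n // 2:
        raise ValueError(f"k_max must be in [1, {n // 2}]")
    X = np.fft.rfft(w.flow)
    mags = 2.0 * np.abs(X[1 : k_max + 1]) / n
    return Spectrum(
        frequencies_hz=np.arange(1, k_max + 1),
        magnitudes=mags,
        compartment=w.compartment,
    )


def calibrate_noise_threshold(background_sds: dict) -> NoiseCalibration:
    """Frequency thresholds: max over subjects of (background SD / 5).

    ``background_sds`` maps compartment -> sequence of per-subject background
    noise SDs (in the same units as the spectra they will be compared to).
    """
    thresholds = {}
    for comp, sds in background_sds.items():
        sds = np.asarray(list(sds), dtype=float)
        if sds.size == 0:
            raise ValueError(f"no background SDs for compartment {comp!r}")
        if np.any(sds <= 0):
            raise ValueError("background SDs must be positive")
        thresholds[comp] = float(np.max(sds) / 5.0)
    return NoiseCalibration(
        thresholds=thresholds,
        per_subject_sds={c: list(map(float, s)) for c, s in background_sds.items()},
    )


def detectability_simulation(
    noise_sd: float = 1.0,
    amplitude_grid: np.ndarray | None = None,
    n_trials: int = 200,
    seed: int = 0,
    n_samples: int = 2000,
    signal_bin: int = 10,
    detection_rate: float = 0.9,
) -> float:
    """Minimal sine amplitude detectable in white noise, as a fraction of
    the noise SD.

    A sinusoid at a known DFT bin is buried in white Gaussian noise and its
    amplitude reduced stepwise from one noise SD toward zero. At each
    amplitude the sine counts as detected in a trial when its bin magnitude
    exceeds every other nonzero bin's magnitude; an amplitude is detectable
    when this happens in at least ``detection_rate`` of trials. Returns the
    smallest detectable amplitude (fraction of the noise SD), scanning
    downward and stopping at the first failure.

    The default record is 2000 samples (twenty nominal cycles at the 10 ms
    analysis interval), for which the minimal detectable fraction comes out
    near one fifth.
    """
    if n_trials < 20:
        raise ValueError("need at least 20 trials per amplitude")
    if amplitude_grid is None:
        amplitude_grid = np.arange(1.0, 0.0, -0.05)
    amplitude_grid = np.asarray(amplitude_grid, dtype=float)
    if np.any(np.diff(amplitude_grid) >= 0) or np.any(amplitude_grid <= 0):
        raise ValueError("amplitude grid must be descending within (0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples)
    carrier = np.sin(2.0 * np.pi * signal_bin * t / n_samples)
    smallest = None
    for frac in amplitude_grid:
        hits = 0
        for _ in range(n_trials):
            x = frac * noise_sd * carrier + rng.normal(0.0, noise_sd, n_samples)
            mags = np.abs(np.fft.rfft(x)[1:])
            if np.argmax(mags) == signal_bin - 1:
                hits += 1
        if hits / n_trials >= detection_rate:
            smallest = float(frac)
        else:
            break
    if smallest is None:
        raise RuntimeError("no amplitude on the grid was detectable")
    return smallest
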