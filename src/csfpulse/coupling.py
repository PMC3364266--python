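"""Arterial-to-CSF transfer-function identification and pulse-latency
estimation.

The transfer from cerebral arterial inflow to spinal or aqueductal CSF flow
is modeled as a discrete-time, causal, fifth-order rational system
(output-error structure) identified with a prediction-error method: the
parameters minimize the simulation-error sum of squares between the
measured CSF output and the model output driven by the arterial input.
Because gated waveforms are one periodic cycle, simulation error is
evaluated in the frequency domain (per-harmonic multiplication is the
steady-state response of an LTI system to a periodic input; by Parseval the
two costs are equivalent).

Pulse transmission latency is estimated independently of any model by the
lag maximizing the circular cross-correlation of the arterial waveform with
the negated (caudal-positive) CSF waveform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .waveform import FlowWaveform

__all__ = [
    "TransferFunctionModel",
    "BodeCurve",
    "CrossCorrelationResult",
    "NOISE_LIMIT_HZ",
    "identify_tf",
    "bode",
    "crossover_frequency",
    "cross_correlate",
    "transmission_delay",
]

#: Frequency above which transfer-function values are noise-dominated.
NOISE_LIMIT_HZ = {"spinal": 7.0, "aqueduct": 5.0}


@dataclass
class TransferFunctionModel:
    """Discrete-time rational model B(z)/F(z), F monic, at a 10 ms interval."""

    b: np.ndarray  # numerator, b[0] + b[1] z^-1 + ...
    f: np.ndarray  # denominator, 1 + f[1] z^-1 + ... (f[0] == 1)
    dt_ms: float = 10.0
    residual_variance: float = float("nan")
    variance_accounted_pct: float = float("nan")
    converged: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.f[0] != 1.0:
            raise ValueError("denominator must be monic")

    @property
    def nyquist_hz(self) -> float:
        return 500.0 / self.dt_ms

    def poles(self) -> np.ndarray:
        return np.roots(self.f)

    def is_stable(self) -> bool:
        p = self.poles()
        return p.size == 0 or bool(np.all(np.abs(p) < 1.0))

    def frequency_response(self, freqs_hz) -> np.ndarray:
        """Complex response on the unit circle at the given frequencies."""
        freqs_hz = np.asarray(freqs_hz, dtype=float)
        z1 = np.exp(-2j * np.pi * freqs_hz * self.dt_ms / 1000.0)  # z^-1
        num = np.polyval(self.b[::-1], z1)
        den = np.polyval(self.f[::-1], z1)
        return num / den


@dataclass
class BodeCurve:
    frequencies_hz: np.ndarray
    gain: np.ndarray
    phase_rad: np.ndarray  # unwrapped
    noise_limit_hz: float | None = None

    def __post_init__(self):
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.gain = np.asarray(self.gain, dtype=float)
        self.phase_rad = np.asarray(self.phase_rad, dtype=float)


@dataclass
class CrossCorrelationResult:
    lags_ms: np.ndarray
    values: np.ndarray
    delay_ms: float  # parabolic-refined argmax
    peak_value: float


def _check_grid(*ws: FlowWaveform):
    n = ws[0].n_samples
    for w in ws:
        if not w.time_normalized:
            raise ValueError("waveforms must be time-normalized to a common grid")
        if w.n_samples != n:
            raise ValueError("waveforms must share one sample grid")
    return n


def _stabilize(f: np.ndarray, b: np.ndarray):
    """Reflect unstable poles into the unit circle, rescaling the numerator
    so the magnitude response is unchanged (|1 - p/|p|^2 z^-1| differs from
    |1 - p z^-1| by exactly 1/|p| on the unit circle)."""
    roots = np.roots(f)
    scale = 1.0
    changed = False
    for i, p in enumerate(roots):
        m = abs(p)
        if m >= 1.0:
            roots[i] = p / (m * m + 1e-12)
            scale /= m
            changed = True
    if not changed:
        return f, b
    f_new = np.real(np.poly(roots))
    return np.concatenate([[1.0], f_new[1:]]), b * scale


def _oe_cost(theta, nb, U, Y, z1):
    b, fden = theta[:nb], np.concatenate([[1.0], theta[nb:]])
    H = np.polyval(b[::-1], z1) / np.polyval(fden[::-1], z1)
    r = Y - H * U
    return float(np.sum(r.real**2 + r.imag**2)), H


def identify_tf(
    input_w: FlowWaveform,
    output_w: FlowWaveform,
    order: int = 5,
    max_iter: int = 100,
    cost_tol: float = 1e-8,
    band_limit_hz: float | None = None,
) -> TransferFunctionModel:
    """Prediction-error identification of a causal output-error model.

    The model has ``order`` zeros and ``order`` poles (numerator b0..b_order,
    monic denominator). The fit includes the zero-frequency bin, i.e. the
    signal means are part of the data: the DC gain of the model is anchored
    by the ratio of the mean output to the mean input, which keeps the
    low-frequency end of the identified response determined by data rather
    than extrapolation. Parameters are initialized by a circular
    equation-error (ARX) least squares fit and refined by damped
    Gauss-Newton on the simulation-error sum of squares; any unstable pole
    is reflected into the unit circle with a gain-preserving numerator
    rescale. When ``band_limit_hz`` is given, the simulation-error cost is
    restricted to harmonics at or below that frequency (components beyond
    the compartment noise limit carry no signal and would otherwise bias
    the fit).
    """
    n = _check_grid(input_w, output_w)
    u = input_w.flow
    y = output_w.flow
    if np.allclose(u, u.mean()):
        raise ValueError("constant input: system unidentifiable")
    dt_ms = float(np.diff(input_w.times_ms)[0])
    nb = order + 1

    # circular ARX initialization: y[t] = sum b_i u[t-i] - sum f_i y[t-i]
    cols = [np.roll(u, i) for i in range(nb)] + [-np.roll(y, i) for i in range(1, order + 1)]
    A = np.stack(cols, axis=1)
    theta0, *_ = np.linalg.lstsq(A, y, rcond=None)
    f0, b0 = _stabilize(np.concatenate([[1.0], theta0[nb:]]), theta0[:nb])
    theta = np.concatenate([b0, f0[1:]])

    U = np.fft.rfft(u)
    Y = np.fft.rfft(y)
    k = np.arange(U.size)
    if band_limit_hz is not None:
        dur_s = n * dt_ms / 1000.0
        # keep DC plus at least order+1 harmonics (overdetermined fit)
        n_harm = max(int(np.floor(band_limit_hz * dur_s)), order + 1)
        if n_harm >= k.size:
            raise ValueError("band limit exceeds the available harmonics")
        U, Y, k = U[: n_harm + 1], Y[: n_harm + 1], k[: n_harm + 1]
    z1 = np.exp(-2j * np.pi * k / n)

    cost, H = _oe_cost(theta, nb, U, Y, z1)
    converged = False
    for _ in range(max_iter):
        b, fden = theta[:nb], np.concatenate([[1.0], theta[nb:]])
        Fz = np.polyval(fden[::-1], z1)
        Bz = np.polyval(b[::-1], z1)
        # Jacobian of H*U wrt parameters
        pows = z1[None, :] ** np.arange(nb)[:, None]
        Jb = (pows / Fz) * U  # (nb, K)
        Jf = -(z1[None, :] ** np.arange(1, order + 1)[:, None]) * (Bz / Fz**2) * U
        J = np.vstack([Jb, Jf]).T  # (K, nparams) complex
        r = Y - (Bz / Fz) * U
        Jri = np.vstack([J.real, J.imag])
        rri = np.concatenate([r.real, r.imag])
        step, *_ = np.linalg.lstsq(Jri, rri, rcond=None)
        # damped acceptance with stability projection
        accepted = False
        lam = 1.0
        for _ in range(25):
            cand = theta + lam * step
            fc, bc = _stabilize(np.concatenate([[1.0], cand[nb:]]), cand[:nb])
            cand = np.concatenate([bc, fc[1:]])
            c_new, _ = _oe_cost(cand, nb, U, Y, z1)
            if c_new < cost:
                accepted = True
                break
            lam *= 0.5
        if not accepted:
            converged = True
            break
        rel = (cost - c_new) / max(cost, 1e-300)
        theta, cost = cand, c_new
        if rel < cost_tol:
            converged = True
            break

    b, fden = theta[:nb], np.concatenate([[1.0], theta[nb:]])
    fden, b = _stabilize(fden, b)
    ss_y = float(np.sum(np.abs(Y[1:]) ** 2))  # fitted-band pulsatile energy
    vaf = 100.0 * (1.0 - cost / ss_y) if ss_y > 0 else float("nan")
    return TransferFunctionModel(
        b=b,
        f=fden,
        dt_ms=dt_ms,
        residual_variance=2.0 * cost / n**2,
        variance_accounted_pct=vaf,
        converged=converged,
        meta={
            "order": order,
            "input_mean": float(input_w.flow.mean()),
            "output_mean": float(output_w.flow.mean()),
        },
    )


def bode(model: TransferFunctionModel, freqs_hz, noise_limit_hz: float | None = None) -> BodeCurve:
    """Gain and unwrapped phase of the model on the unit circle."""
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    if np.any(freqs_hz <= 0) or np.any(freqs_hz > model.nyquist_hz):
        raise ValueError(f"frequencies must lie in (0, {model.nyquist_hz}] Hz")
    H = model.frequency_response(freqs_hz)
    return BodeCurve(
        frequencies_hz=freqs_hz,
        gain=np.abs(H),
        phase_rad=np.unwrap(np.angle(H)),
        noise_limit_hz=noise_limit_hz,
    )


def crossover_frequency(curve: BodeCurve) -> float:
    """Frequency where the gain falls below unity from above, linearly
    interpolated between grid points; NaN when the gain never crosses
    unity downward.

    The crossing is located at or after the gain curve's maximum: a
    low-pass characteristic crosses unity once past its peak, and anchoring
    the search there keeps small sub-peak wiggles of a noisy fit from
    masquerading as the crossover.
    """
    g, f = curve.gain, curve.frequencies_hz
    above = g >= 1.0
    start = int(np.argmax(g))
    for i in range(start, len(g) - 1):
        if above[i] and not above[i + 1]:
            g0, g1 = g[i], g[i + 1]
            return float(f[i] + (g0 - 1.0) / (g0 - g1) * (f[i + 1] - f[i]))
    return float("nan")


def cross_correlate(input_w: FlowWaveform, output_w: FlowWaveform) -> CrossCorrelationResult:
    """Normalized circular cross-correlation over all lags of the common grid.

    ``values[l]`` correlates the input with the output advanced by lag l,
    i.e. it peaks at l = L when the output is the input delayed by L. Both
    signals are mean-removed and scaled to unit variance, so a circularly
    shifted copy attains exactly 1 at its shift.
    """
    n = _check_grid(input_w, output_w)
    dt = float(np.diff(input_w.times_ms)[0])
    x = input_w.flow - input_w.flow.mean()
    y = output_w.flow - output_w.flow.mean()
    sx, sy = np.sqrt(np.sum(x**2)), np.sqrt(np.sum(y**2))
    if sx == 0 or sy == 0:
        raise ValueError("zero-variance waveform")
    r = np.fft.irfft(np.conj(np.fft.rfft(x)) * np.fft.rfft(y), n) / (sx * sy)
    lags = np.arange(n) * dt
    i = int(np.argmax(r))
    # parabolic refinement on the circular 3-point neighborhood; exact for
    # on-grid shifts because the correlation is even about the true lag
    rm, r0, rp = r[(i - 1) % n], r[i], r[(i + 1) % n]
    denom = rm - 2 * r0 + rp
    frac = 0.0 if denom == 0 else 0.5 * (rm - rp) / denom
    frac = float(np.clip(frac, -0.5, 0.5))
    delay = (i + frac) * dt % (n * dt)
    return CrossCorrelationResult(
        lags_ms=lags, values=r, delay_ms=float(delay), peak_value=float(r0)
    )


def transmission_delay(arterial_w: FlowWaveform, csf_w: FlowWaveform) -> dict:
    """Delay of peak caudal CSF flow behind peak arterial flow, in ms.

    Primary estimate: lag maximizing the circular cross-correlation of the
    arterial waveform with the negated (caudal-positive) CSF waveform.
    Secondary estimate: time of maximum caudal CSF flow minus time of the
    arterial maximum, modulo the cycle.
    """
    neg = csf_w.copy(flow=-csf_w.flow)
    xc = cross_correlate(arterial_w, neg)
    n = arterial_w.n_samples
    period = n * float(np.diff(arterial_w.times_ms)[0])
    t_art = arterial_w.times_ms[int(np.argmax(arterial_w.flow))]
    t_csf = csf_w.times_ms[int(np.argmin(csf_w.flow))]
    return {
        "delay_ms": xc.delay_ms,
        "peak_to_peak_ms": float((t_csf - t_art) % period),
        "correlation": xc,
    }
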