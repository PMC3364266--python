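# Methods

`csfpulse` implements a complete analysis chain for cardiac-gated
phase-contrast MRI flow data in three compartments — cerebral arterial
inflow (carotid + vertebral), cervical spinal CSF at C3–C4, and aqueductal
CSF — together with a synthetic-data generator that emulates such
acquisitions so that every stage can be verified without patient data.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Image-domain processing

**Velocity encoding and aliasing.** Stored velocities live in
(−venc, +venc]; true velocities beyond the encoding velocity wrap by
multiples of 2·venc. Aliasing is corrected by temporal phase unwrapping
per pixel: velocities are mapped to phase with ±venc = ±π and consecutive
frame-to-frame jumps larger than π are corrected by ±2π steps
(`numpy.unwrap` semantics). The unwrap axis is time: in a gated cine
series at fixed venc, aliasing manifests as temporal jumps at the systolic
peak. The operation is idempotent and leaves non-aliased pixels unchanged.
It fails silently only if the true velocity changes by more than venc
between consecutive frames, which bounds the admissible frame spacing.

**Segmentation.** Lumina are segmented by Otsu's histogram threshold on
the magnitude image inside a user-drawn ROI polygon, keeping the largest
connected foreground component. Arteries are segmented frame by frame
(their cross-section pulses); the aqueduct from a single reference frame —
by default the frame with maximum velocities inside the ROI. The Otsu
level maximizes between-class variance over a 256-bin histogram; when the
optimum is a plateau (empty gray-level gap between well-separated modes)
the plateau midpoint is returned, so the threshold sits between the modes
rather than at the edge of one. The cervical spinal canal, whose magnitude
contrast is poor, is segmented from temporal frequency content instead:
per voxel, the non-zero-frequency energy of the velocity time course
(equivalently the RMS pulsatile amplitude) is thresholded by the same Otsu
rule, which makes the mask invariant to a rescaling of the pulsatile
amplitude. A static ROI is rejected when the foreground's mean pulsatile
amplitude does not exceed three times the background's (pure noise splits
its own distribution without meaning).

**Rim-based QC and threshold iteration.** Two one-pixel rims adjacent to
the mask boundary verify the segmentation: the outer rim (dilation shell)
must not carry pulsatile velocity beyond 3× the background noise SD (else
lumen signal leaks outside: grow the mask), and the inner rim (erosion
shell) must carry velocity consistent with the mask interior (mean at
least 25% of the in-mask mean, else the mask overreaches: shrink). Rim
content is judged on the temporal-fluctuation magnitude so that a static
background phase offset is not mistaken for lumen signal. The
semi-automatic loop rescales the Otsu level by ±5% per iteration, up to 10
iterations, in the direction the rim report suggests. The 3× and 25%
bounds and the ±5% schedule are package choices; the underlying visual
criterion they replace is not quantitative.

**Background phase correction** subtracts the temporal-mean velocity of a
reference region from every pixel of every frame: a rectangle near the ROI
(arteries, aqueduct) or the one-voxel contour adjacent to the mask (spinal
canal, where no clean rectangle exists). The correction is exactly linear.

**Flow integration.** Volumetric flow per frame is the pixel area times
the sum of in-mask velocities (1 cm/s over 1 mm² = 0.01 mL/s). On a
noise-free phantom with the true mask this reproduces the generator's
waveform to numerical precision, which is the package's core round-trip
invariant.

## Waveform analysis

**Scalar metrics.** The average flow rate is the cycle time-average of
|Q| (trapezoidal, closing the cycle periodically), reported in mL/min; the
net flow rate is the signed counterpart. The stroke volume is the mean of
the absolute areas under the two flow directions, in µL; a missing lobe
contributes zero. Clinical reference thresholds (42 µL aqueductal stroke
volume, 18 mL/min average flow) are carried in the pipeline configuration
and reported as flags, not hard limits.

**Amplitude normalization** divides CSF waveforms by their own cycle
average of |Q| (making that average exactly 1) and arterial waveforms by
the mean |Q| of the systolic phase only, because systole has a nearly
heart-rate-invariant duration while diastole varies. Systole is delimited
as R-wave to the minimum at aortic valve closure (feature ar5); the
boundary is carried on the waveform as `systole_end_ms`.

**Temporal normalization** maps every cycle onto a nominal 1 s cycle
sampled at 10 ms without stretching systole: short cycles are extended by
a linear diastolic tail running from the last sample's value back to the
first sample's value at t = 1 s; long cycles have end-diastolic content
beyond 1 s dropped. Resampling is linear; the operation is idempotent and
exactly the identity on already-normalized input. All frequency-domain and
coupling analyses run on the normalized grid, where every subject's
harmonics fall on integer frequencies.

**Feature points** (arterial ar1–ar6, spinal sp1–sp6, aqueductal aq1–aq5)
are located as sign changes of the first difference (extrema) and second
difference (inflections) of a minimally smoothed copy (circular 3-point
moving average); amplitudes are read from the unsmoothed waveform; labels
are assigned by the canonical temporal ordering. All six arterial labels
are required; the aqueductal inflection labels are optional because a
smooth near-sinusoidal cycle possesses only two inflections. Characteristic
curves through feature points use shape-preserving piecewise-cubic Hermite
(PCHIP) interpolation, which cannot overshoot on monotone segments.

## Spectral analysis and noise calibration

Harmonic magnitudes are single-sided amplitudes 2|X_k|/N for k = 1…K (a
unit sine at an integer frequency has magnitude 1); the zero-frequency bin
is excluded from reporting because after amplitude normalization it no
longer measures net flow. Reported component counts are 10 (arterial), 7
(spinal) and 5 (aqueduct).

The noise threshold below which a component is indistinguishable from
noise is one fifth of the background-noise SD, maximized over subjects per
compartment. The one-fifth factor is reproduced from first principles by
`detectability_simulation`: a sine of known bin in unit white noise is
declared detected in a trial when its bin magnitude exceeds every other
bin's, and an amplitude is detectable when that happens in ≥90% of trials.
The detection criterion and the 90% rate are package choices. The record
length matters: the expected maximum of the noise bins' Rayleigh-
distributed magnitudes falls with record length, and the default of 2000
samples (twenty nominal cycles at the 10 ms interval) is the plateau at
which the detectable fraction stabilizes at ≈0.2.

## Transfer-function identification

The arterial-to-CSF transfer is modeled as a discrete-time, causal,
stable, fifth-order output-error system y = B(z)/F(z)·u at the 10 ms
interval, estimated by a prediction-error method: parameters minimize the
simulation-error sum of squares. Because the gated waveforms are one
periodic cycle, the steady-state response of an LTI system is per-harmonic
multiplication, and the cost is evaluated in the frequency domain
(equivalent by Parseval). Numerical scheme: circular equation-error (ARX)
least-squares initialization, then damped Gauss–Newton (step halving, at
most 100 iterations, relative cost tolerance 1e−8); after every accepted
step, unstable poles are reflected into the unit circle with an exact
gain-preserving numerator rescale, so every returned model is stable and
causal by construction.

Two choices deserve emphasis:

- **The DC bin is part of the data.** The ratio of mean output to mean
  input anchors the model's zero-frequency gain. Without it, everything
  the model does below the fundamental (1 Hz after normalization) is pure
  extrapolation, and the unity-gain crossover of a low-pass transfer — a
  quantity that for these couplings lies at or below the fundamental — is
  numerically meaningless.
- **The fit is band-limited** to the compartment's noise-limit frequency
  (7 Hz spinal, 5 Hz aqueduct; never fewer than order+1 harmonics, so the
  fit stays overdetermined). Components beyond the noise limit carry no
  signal, and including them lets measurement noise tilt the model.

Gain and phase are evaluated on the unit circle on a 0.05 Hz grid up to
the noise limit. The **crossover frequency** is the downward unity
crossing of the gain, linearly interpolated between grid points, searched
at or after the gain curve's maximum: a low-pass characteristic crosses
unity once past its peak, and anchoring the search there prevents sub-peak
wiggles of a noisy fit from masquerading as the crossover. Curves that
never cross are flagged NaN and excluded from group summaries (with their
count reported).

## Cross-correlation latency

Pulse-transmission delay is estimated model-free as the lag maximizing the
normalized circular cross-correlation of the arterial waveform with the
negated (caudal-positive) CSF waveform, both mean-removed and
unit-variance scaled, over all 100 lags of the normalized grid. The peak
is refined by a 3-point parabolic fit on the circular neighborhood: for a
copy shifted by a whole number of samples, the correlation is even about
the true lag, so the refinement returns the grid lag exactly, while
off-grid lags (the packaged 34 ms and 132 ms values) are recovered without
grid quantization. A secondary peak-to-peak estimate (time of maximum
caudal CSF flow minus time of the arterial maximum, modulo the cycle) is
reported alongside. Circular rather than zero-padded correlation is the
natural choice for one periodic cycle.

## Synthetic-data generator

**Templates.** Group-specific (young/elderly) characteristic waveforms are
parameterized by the leading harmonics of anchor-point morphologies
(PCHIP through packaged anchor nodes): a sharp systolic arterial peak with
dicrotic structure, biphasic caudal-dominant CSF pulses, smoother and more
sinusoidal elderly shapes, and more high-harmonic energy in the young
templates (12 vs 8 arterial harmonics). The anchors are synthetic,
qualitative shape calibrations — not digitized measurements — and the
amplitudes carry packaged physical scales placing cohort metrics in the
physiological range. Heart-rate variation is absorbed entirely by the
diastolic tail at generation, mirroring the analysis-side normalization:
the systolic segment is identical at every heart period.

**Coupling.** Each CSF waveform is the normalized arterial waveform passed
through a stable, causal, fifth-order rational system: a bilinear-
discretized second-order resonant low-pass (natural frequency f0, damping
ζ = 0.25, small DC gain g0 of 0.05 spinal / 0.10 aqueduct representing the
net-flow path) in cascade with three first-order all-pass sections whose
common pole sets the bulk transmission delay. The response is constructed
on the temporally normalized grid — exactly where the identification
stage operates, so the input–output pair lies exactly in the fitted model
class — and is then restricted back to the subject's native cycle.

Because amplitude normalization divides a CSF waveform by its own cycle
average of |Q|, the transfer gain the pipeline sees is fixed by the
waveform's shape and cannot be set by scaling the filter. The generator
therefore *calibrates* its parameters per subject, deterministically:

1. the all-pass pole is solved (Brent) so the measured circular
   cross-correlation delay equals the prescribed lag;
2. f0 is solved so the low-pass gain divided by the normalization scale
   crosses unity at the prescribed crossover frequency, then polished
   against the actual identification chain (which absorbs the residual
   distortion that diastole-extension introduces for off-nominal heart
   periods);
3. a small residual phase ramp (a few ms) zeroes the remaining delay
   bias, and the sign branch — whether the caudal pulse rides the
   in-phase or anti-phase flank of the resonance — is chosen to minimize
   that residual.

The packaged group calibration values are: transmission lags 55/160 ms
(young spinal/aqueduct) and 34/132 ms (elderly), crossover frequencies
0.5/0.8 Hz (young) and 3.0/0.5 Hz (elderly). End-to-end runs are thus
construction-parameter recovery checks.

**Phantom images.** Velocity series realize a waveform with a parabolic
in-lumen profile scaled per frame so the true-mask-integrated flow equals
the waveform value exactly, a planar background velocity offset, white
Gaussian noise, wrapping into (−venc, +venc], and binary magnitude
contrast suitable for thresholding. Geometries mirror the acquisition
settings (0.8×0.7 mm² at venc 100 cm/s arterial, 12 cm/s spinal;
0.4×0.4 mm² at venc 15 cm/s aqueduct; 22–64 frames per cycle). Parabolic
rather than Womersley profiles are used because only the integrated flow
matters downstream.

**Cohorts.** Default cohorts have 11 subjects per group, heart periods
drawn from a normal distribution (mean 831 ms, SD 169 ms) truncated to
[500, 1200] ms, ages uniform in 21–29 (young) and 64–81 (elderly),
alternating sexes with a male > female offset in CSF flow amplitude, and
log-normal between-subject spread of the CSF amplitude scale (which
cancels in all normalized analyses). Waveform measurement noise defaults
to roughly 1% of each compartment's pulsatile flow SD — composite cycles
from retrospective gating average hundreds of beats, so residual noise on
the gated flow curve is far below single-image noise.

### What the generator does and does not emulate

Passing the end-to-end checks demonstrates that the pipeline recovers the
statistical structure it is built to measure — lags, transfer gains,
harmonic content, scalar metrics — from data with realistic geometry,
heart-rate variability and noise. It does **not** demonstrate performance
on real physiology. Known departures:

- The coupling is exactly LTI and exactly fifth-order; real arterial-CSF
  coupling is neither, and real identification residuals are larger.
- The calibrated CSF waveforms are dominated by their net (DC) component
  with a comparatively small pulsatile ripple, i.e. they are nearly
  unidirectional. Real spinal CSF flow oscillates around approximately
  zero net flow. This is a structural consequence of demanding that the
  *normalized-domain* transfer gain cross unity below the fundamental:
  with cycle-average amplitude normalization, a zero-mean output forces
  the gain at the fundamental above one, making sub-fundamental crossovers
  unattainable. The generated waveforms trade this aspect of realism for
  exact construction-parameter recovery.
- Template morphologies are qualitative; feature-point amplitudes and
  timings are not digitized group means.
- No MR physics (k-space, eddy currents) and no 3D anatomy; the background
  phase error is a static plane.

## Statistics

Group comparisons use the two-sided Mann-Whitney U test (exact by
enumeration when the combined sample is ≤12 without ties — the study scale
of 11 + 11 sits just above — otherwise the tie-corrected normal
approximation), Spearman's rank correlation with mid-ranks, and mixed
repeated-measures ANOVA with Greenhouse-Geisser correction: epsilon =
(Σλ)²/((k−1)Σλ²) from the eigenvalues of the double-centered covariance of
the repeated measures, floored at 1/(k−1); within-subject and interaction
degrees of freedom are multiplied by epsilon before the p computation.
With k = 2 measures epsilon is exactly 1. Non-normally distributed
variables are log-transformed first, screened by Shapiro-Wilk at 0.05.
Under a seeded spherical null (12 subjects, 4 measures, 1000 replicates)
the corrected within-effect test rejects at 3–5%, i.e. the correction is
mildly conservative, as expected.

## Problem sizes and numerical defaults

Analyses run on 100-sample normalized cycles; cohorts of 11 subjects per
group; identification uses ≤8 harmonics + DC with ≤100 Gauss-Newton
iterations; the detectability simulation uses 200 trials per amplitude on
a 2000-sample record; the type-I calibration uses 1000 replicates. A full
two-cohort study, including per-subject coupling calibration, completes in
well under a minute on one core. All randomness flows from explicit seeds;
identical (configuration, seed) pairs reproduce reports byte for byte.

## Known limitations

- Sub-fundamental crossover estimates are extrapolations stabilized by the
  DC anchor; on noisy data individual subjects can still yield undefined
  or outlying crossings (flagged, not silently dropped). Group means carry
  correspondingly wide SDs.
- The exact-recovery guarantees hold on the 10 ms analysis grid; input
  waveforms sampled more coarsely are linearly interpolated.
- The rim-check bounds and the frequency-segmentation separation factor
  are heuristics chosen for the synthetic phantoms' contrast and noise
  regime; real acquisitions may need the exposed scale parameters.
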