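# csfpulse

Quantification of cerebral arterial inflow and cerebrospinal fluid (CSF)
dynamics from cardiac-gated phase-contrast MRI, and analysis of their
coupling.

Cerebral arterial inflow drives pulsatile CSF motion in the cervical
spinal canal and the aqueduct of Sylvius; how strongly and how fast that
pulse is transmitted changes with age and is clinically relevant for
conditions such as normal pressure hydrocephalus. `csfpulse` implements
the full analysis chain for such studies:

- **image domain**: velocity-aliasing correction (temporal phase unwrap at
  the encoding velocity), semi-automatic lumen segmentation (Otsu
  threshold with rim-based QC; temporal-frequency segmentation for the
  spinal canal), background phase correction, and flow integration
  Q(t) = A·Σv over the lumen mask;
- **waveform domain**: clinical scalar metrics (cycle-average flow rate in
  mL/min, stroke volume in µL), amplitude normalization (CSF by the cycle
  average of |Q|, arterial by the systolic-phase average), temporal
  normalization onto a nominal 1 s cycle at 10 ms that preserves systole
  and extends/truncates diastole, labeled feature points (ar1–ar6,
  sp1–sp6, aq1–aq5) and PCHIP characteristic curves;
- **frequency domain**: single-sided harmonic amplitudes 2|X_k|/N on
  integer frequencies, with a simulation-calibrated noise threshold (one
  fifth of the background-noise SD);
- **coupling**: fifth-order output-error transfer functions B(z)/F(z)
  identified by the prediction-error method (stable and causal by
  construction), Bode gain/phase, unity-gain crossover frequency, and
  model-free transmission delays from circular cross-correlation;
- **statistics**: Mann-Whitney (exact for small samples), Spearman's rho,
  mixed repeated-measures ANOVA with Greenhouse-Geisser correction, and a
  Shapiro-Wilk/log-transform screen;
- **synthetic data**: a first-class generator producing coupled
  arterial/spinal/aqueductal waveforms and phase-contrast-like velocity
  image series whose construction parameters (transmission lags, transfer
  crossover frequencies, noise levels, geometry) are known exactly, so
  every pipeline stage is verifiable end to end without patient data.

## Worked example

```python
from csfpulse import PipelineConfig, run_cohort_study

report = run_cohort_study(PipelineConfig(seed=0, n_subjects=11))
young = report["groups"]["young"]["summary"]
elderly = report["groups"]["elderly"]["summary"]
print(round(young["aqueduct_delay_ms"]["mean"], 1),
      round(elderly["spinal_delay_ms"]["mean"], 1),
      round(young["spinal_crossover_hz"]["mean"], 2))
```

prints

```
159.9 34.1 0.47
```

meaning: on the default seeded synthetic cohorts the full pipeline
(normalization → identification → cross-correlation) recovers the young
group's 160 ms arterial-to-aqueduct transmission lag and the elderly
group's 34 ms arterial-to-spinal lag essentially exactly, and estimates
the young arterial-to-spinal transfer's unity-gain crossover at ≈0.5 Hz —
all three being the generator's construction parameters. The report also
carries per-subject scalar metrics with the clinical 42 µL / 18 mL/min
flags, feature points, spectra, transfer-function diagnostics, and the
between-group statistics.

The `examples/` directory holds one short narrative script per
capability (cohort simulation, image-to-flow, waveform metrics, coupling
analysis, group statistics, noise calibration); each prints the numbers
it computes and what they mean.

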