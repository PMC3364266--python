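"""From cine phase-contrast velocity images to a volumetric flow waveform.

Builds a synthetic arterial acquisition (parabolic lumen profile, planar
background phase offset, velocity wrapping at venc, noise), then runs the
image chain: temporal phase unwrapping, Otsu segmentation with rim-based
QC, background phase correction, and flow integration. The recovered
waveform is compared with the generator's ground truth.
"""

import numpy as np

from csfpulse import (
    GeometrySpec,
    RoiPolygon,
    compute_flow,
    correct_background,
    iterative_segmentation,
    unwrap_velocity,
)
from csfpulse.synthetic import generate_waveform, synthesize_velocity_series
from csfpulse.templates import default_template

truth = generate_waveform(default_template("arterial", "young"), 831.0)
geometry = GeometrySpec(
    shape=(64, 64), center=(32, 32), radius_px=5.0, pixel_mm=(0.8, 0.7),
    venc_cm_s=100.0, ramp=(1.2, 0.01, 0.0),  # background phase offset plane
)
series = synthesize_velocity_series(truth, geometry, n_frames=40, noise_sd=0.3, seed=1)
print(f"synthesized {series.n_frames} frames, venc {series.venc_cm_s} cm/s, "
      f"stored velocities within [{series.phase.min():.0f}, {series.phase.max():.0f}] cm/s")

unwrapped = unwrap_velocity(series)
roi = RoiPolygon.rectangle(20, 20, 44, 44)
mask, rim = iterative_segmentation(unwrapped, roi, mode="per_frame")
print(f"segmentation: {mask.masks[0].sum()} px in frame 0, rim check "
      f"{'passed' if rim.passed else 'failed'} ({rim.suggestion})")

corrected = correct_background(unwrapped, mask, "rectangle", (2, 12, 2, 12))
flow = compute_flow(corrected, mask)

expected = truth.sample_periodic(series.frame_times_ms)
err = np.max(np.abs(flow.flow - expected)) / np.abs(expected).max()
print(f"peak flow {flow.flow.max():.1f} mL/s (truth {expected.max():.1f} mL/s)")
print(f"relative flow error {100 * err:.2f}% — the image chain recovers the "
      "generator's waveform to within the segmentation's boundary pixels.")
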