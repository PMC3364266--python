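"""Transfer-function identification and pulse-latency estimation for one
synthetic subject.

The arterial-to-CSF coupling is characterized two ways: a fifth-order
output-error model fit by the prediction-error method (gain/phase versus
frequency, unity-gain crossover) and a model-free circular
cross-correlation (transmission delay of the caudal CSF pulse).
"""

import numpy as np

from csfpulse import (
    bode,
    crossover_frequency,
    identify_tf,
    normalize_amplitude,
    normalize_time,
    transmission_delay,
)
from csfpulse.synthetic import generate_coupled_subject
from csfpulse.templates import default_cohort_spec, default_coupling, default_template

templates = {c: default_template(c, "elderly") for c in ("arterial", "spinal", "aqueduct")}
arterial, spinal, aqueduct = generate_coupled_subject(
    templates, default_coupling("elderly"), default_cohort_spec("elderly"),
    seed=4, heart_period_ms=860.0,
)

u = normalize_time(normalize_amplitude(arterial, "systolic_average"))
for name, csf, limit in (("spinal", spinal, 7.0), ("aqueduct", aqueduct, 5.0)):
    y = normalize_time(normalize_amplitude(csf, "cc_average"))
    model = identify_tf(u, y, order=5, band_limit_hz=limit)
    curve = bode(model, np.arange(0.05, limit + 1e-9, 0.05), noise_limit_hz=limit)
    fco = crossover_frequency(curve)
    delay = transmission_delay(u, y)
    print(f"\narterial -> {name}:")
    print(f"  model stable: {model.is_stable()}, "
          f"variance accounted: {model.variance_accounted_pct:.2f}%")
    print(f"  unity-gain crossover: {fco:.2f} Hz "
          f"(construction value {csf.meta['crossover_hz']} Hz)")
    print(f"  cross-correlation delay: {delay['delay_ms']:.1f} ms "
          f"(construction value {csf.meta['lag_ms']} ms)")
    print(f"  peak-to-peak delay estimate: {delay['peak_to_peak_ms']:.0f} ms")

print("\nThe model-free delay recovers the construction lag almost exactly; "
      "the identified-model crossover scatters around its construction value "
      "(it extrapolates the fitted gain below the fundamental).")
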