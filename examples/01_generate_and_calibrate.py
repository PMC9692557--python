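"""Generate one synthetic subject, quantise to ADC counts, and calibrate back.

Shows the signal path a real recording takes: 16-bit ADC counts on disk,
then the device transfer function back to millivolts.
"""

import numpy as np

from asfemg.calibration import adc_to_millivolts
from asfemg.synth import SubjectProfile, generate_recording, to_adc

profile = SubjectProfile(subject_id="DEMO-001", rng_seed=42)
rec = generate_recording(profile, side="non-paretic", reps=10)
raw = to_adc(rec)
back = adc_to_millivolts(raw)

print(f"recording: {rec.n_channels} channels x {rec.n_samples} samples "
      f"({rec.duration_s:.1f} s at {rec.fs_hz:.0f} Hz)")
print(f"millivolt range: [{rec.mv.min():.3f}, {rec.mv.max():.3f}] mV")
print(f"ADC code range:  [{raw.adc.min()}, {raw.adc.max()}] (16-bit)")
err = np.abs(back.mv - rec.mv).max()
print(f"quantisation round-trip error: {err * 1e3:.4f} uV (must be < 1 LSB = 0.046 uV)")
print(f"ground truth: {len(rec.meta['truth']['bursts'])} bursts over "
      f"{len(rec.meta['truth']['blocks'])} gesture blocks")
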