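"""Reconstruct a three-bar resolution target from simulated measurements.

Builds a positive bar target, simulates the full heterodyne single-pixel
acquisition with realistic 0.1% measurement noise, reconstructs amplitude
and phase, and prints a 1-D profile across one element — the standard way
to show that the bars are resolved.
"""

import numpy as np

from spholo import (
    AcquisitionConfig,
    bar_mask,
    bar_target,
    cnr,
    complex_correlation,
    line_profile,
    run_pipeline,
)

side = 64
obj = bar_target(side, bar_width_px=4, n_elements=4)
cfg = AcquisitionConfig(noise_rel=0.001)  # 0.1% relative detector noise

result = run_pipeline(obj, sr=1.0, config=cfg, seed=1)
print(f"records processed : {result.n_records}")
print(f"simulated time    : {result.duration_simulated * 1e3:.1f} ms")
print(f"complex fidelity  : {complex_correlation(result.image, obj):.6f}")

# vertical cut through the first (horizontal-bar) element
profile = line_profile(result.image.amplitude, (4, 10), (32, 10), width_px=3)
plateaus = (profile > 0.5).astype(int)
print(f"profile (>0.5)    : {''.join(str(v) for v in plateaus)}")
print("                    three separated runs of ones = three resolved bars")

mask = bar_mask(side, 4, 4)
value = cnr(result.image.amplitude, mask, (56, 64, 0, 8))
print(f"CNR (bars vs bg)  : {value:.1f}")
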