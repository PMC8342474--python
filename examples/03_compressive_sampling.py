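"""Compressive sensing along the square sampling path.

Acquires a tissue-like complex phantom once at SR=50% with noise, then
reconstructs from nested prefixes of the square path.  Because the path
orders coefficients from low to high spatial frequency, small sampling
ratios keep most of the image structure; under noise a moderate ratio
can even beat a large one because high-order coefficients are noise-
dominated.
"""

import numpy as np

from spholo import (
    AcquisitionConfig,
    HadamardPlan,
    SamplingPlan,
    complex_correlation,
    reconstruct_image,
    run_pipeline,
    tissue_phantom,
)

side = 64
obj = tissue_phantom(side, seed=4, amp_contrast=0.3, phase_range=2.0,
                     correlation_len_px=4.0)
plan = HadamardPlan(side)
cfg = AcquisitionConfig(noise_rel=0.001)

result = run_pipeline(obj, sr=0.5, config=cfg, seed=3)
print("SR      measurements   complex correlation with truth")
for sr in (0.03125, 0.0625, 0.125, 0.25, 0.5):
    sampling = SamplingPlan(plan, sr)
    img = reconstruct_image(result.corrected, plan, sampling)
    corr = complex_correlation(img, obj)
    print(f"{sr * 100:6.3f}%   {len(sampling):6d}        {corr:.4f}")
print("fidelity rises with SR; already high at 12.5% because the phantom's")
print("energy concentrates in the low-frequency shells the path visits first")
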