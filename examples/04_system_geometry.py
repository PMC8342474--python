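"""Derive the optical and timing parameters of the operational modes.

The same calculators behind the `spholo geometry` command: lateral
resolution and field of view follow from the DMD mirror pitch, binning,
the 4f lens pair and the sqrt(2) diagonal mounting factor; the
throughput (SBP-T) is 2 / refresh_time regardless of optics.
"""

from spholo import (
    AcquisitionConfig,
    SystemConfig,
    derive_geometry,
    round_sig,
    timing_report,
)

acq = AcquisitionConfig()
modes = {
    "large-FOV (3x3 binning, 125/125 mm)": SystemConfig(),
    "large-FOV (2x2 binning, 125/125 mm)": SystemConfig(binning=2),
    "high-resolution (3x3, 300/30 mm)": SystemConfig(f_front=300.0, f_rear=30.0),
}
for name, sys_ in modes.items():
    g = derive_geometry(sys_, acq)
    print(f"{name}:")
    print(f"  resolution {round_sig(g.res_x)} x {round_sig(g.res_y)} um, "
          f"FOV {round_sig(g.fov_x)} x {round_sig(g.fov_y)} mm, "
          f"SBP-T {g.sbp_t:.1f} pixels/s")

tim = timing_report(acq, n_patterns=65_536)
print(f"beat period {tim.beat_period * 1e6:.0f} us, "
      f"{tim.cycles_per_pattern:.0f} cycles and {tim.samples_per_pattern:.0f} "
      f"samples per pattern")
print(f"full 256x256 acquisition: {tim.total_time:.2f} s")
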