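"""Mask artifacts on a 70 keV VMI and extract a thermocouple ROI.

Synthesizes one spectral scan of a heated phantom, builds the [0, 80] HU
validity mask (metal > 80 HU, gas < 0 HU excluded), and reads out the 3 mm
spherical ROI at one sensor tip.
"""

import numpy as np

from spectherm import Channel, PhantomConfig, extract_roi_sample, validity_mask
from spectherm.phantom import simulate_temperature_field, synthesize_spectral_volumes

cfg = PhantomConfig(seed=1)
field = simulate_temperature_field(cfg, t=300.0)  # end of heating
vols = synthesize_spectral_volumes(field, cfg, rng=np.random.default_rng(1))

mask = validity_mask(vols[Channel.VMI70])
n_total = mask.data.size
print(f"valid voxels: {mask.data.sum()}/{n_total} "
      f"({100 * mask.data.mean():.1f}% pass the [0, 80] HU window)")

tip = np.asarray(cfg.thermocouple_tips_mm[0])  # 3 mm from the probe shaft
s = extract_roi_sample(vols, mask, tip, radius_mm=3.0, sensor_id="tc1", scan_index=5)
true_t = field.data[tuple(np.rint(tip / np.array(cfg.spacing)).astype(int))]
print(f"ROI at sensor tc1 (tip {tuple(float(v) for v in tip)} mm, "
      f"true T = {true_t:.1f} degC):")
print(f"  voxels kept      : {s.n_voxels} ({s.vol_mm3:.1f} mm^3)")
print(f"  EDW mean +/- SD  : {s.mean(Channel.EDW):.2f} +/- {s.sd(Channel.EDW):.2f} %")
print(f"  conventional HU  : {s.mean(Channel.CONVENTIONAL_HU):.1f}")
print(f"  Z-eff            : {s.mean(Channel.ZEFF):.2f}")
print("\nthe sphere loses part of its volume to the metal mask around the "
      "sensor wire; a fully obscured tip would be flagged excluded instead.")
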