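"""Shift estimation in 3D with an anisotropic observation window.

Simulates the cylindrical-volume benchmark (axial precision twice the
lateral one) and recovers a 3D shift.  The window is an axis-aligned
ellipsoid, stretched by sigma_z / sigma_xy along z, so that axial pairs
are neither over- nor under-collected relative to lateral ones.
"""

from dataclasses import replace

import numpy as np

from msdrift import EASY_3D, MSParams, mean_shift, simulate_shifted_pair

cfg = replace(EASY_3D, seed=7)
table_a, table_b, true_shift = simulate_shifted_pair(cfg)
params = MSParams(r_initial=150.0, scale=(1.0, 1.0, cfg.sigma_z / cfg.sigma_xy))
est = mean_shift(table_a.xy, table_b.xy, params)

print(f"cylinder: radius {cfg.cell_radius} um, height {cfg.cell_height} um, "
      f"sigma_xy {cfg.sigma_xy} nm, sigma_z {cfg.sigma_z} nm")
print(f"true shift : {np.round(true_shift, 2)} nm")
print(f"estimate   : {np.round(est.shift, 2)} nm")
print(f"error      : {np.round(est.shift - true_shift, 2)} nm "
      "(z error ~2x the lateral one, tracking the precisions)")
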