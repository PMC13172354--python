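"""Compute suction viscoelasticity ratios from a displacement curve.

Generates a 2 s suction / 2 s relaxation curve with known elastic (0.5)
and total (0.8) recovery fractions and reads back Uf, Ur, Ua and the
R2/R7 ratios.
"""

import hsetools as h

curve = h.generate_suction_curve(uf=0.3, elastic_fraction=0.5, recovery_fraction=0.8)
r = h.compute_r_parameters(curve, immediate_window_s=0.1)
print(f"Uf = {r.Uf:.3f} mm  (maximum distension under suction)")
print(f"Ur = {r.Ur:.3f} mm  (immediate retraction after release)")
print(f"Ua = {r.Ua:.3f} mm  (total recovery by end of relaxation)")
print(f"R7 = Ur/Uf = {r.R7:.3f}   R2 = Ua/Uf = {r.R2:.3f}")
# R7 is the elastic portion of the response (higher = more elastic,
# less viscous); R2 is the gross elasticity. Both match the generator's
# construction parameters exactly.
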