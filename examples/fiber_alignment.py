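"""Quantify fiber alignment in an image by 2D-FFT radial summation.

Generates stripe images of decreasing coherence at a known fiber angle
and reports the recovered peak angle and the alignment index
((max - median)/median of the normalized angular profile).
"""

import hsetools as h

for coherence in (1.0, 0.5, 0.0):
    img = h.generate_fiber_image(256, 256, angle=30.0, coherence=coherence, seed=3)
    profile = h.radial_summation(h.fft_power(img))
    print(f"coherence {coherence:.1f}: peak angle {profile.peak_angle:6.1f} deg, "
          f"alignment index {profile.alignment_index:8.3f}")
# A coherent image peaks at the true 30-degree fiber axis with a large
# index; pure noise has no dominant orientation and an index near zero.
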