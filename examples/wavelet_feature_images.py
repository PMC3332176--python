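"""Wavelet feature extraction on one color channel.

Decomposes the red channel of a synthetic lesion with a one-level
Daubechies-4 pyramid, prints the subband energies, and contrasts the two
feature images (approximation vs detail magnitude) by how well they
separate lesion from skin.
"""

import numpy as np

from dermseg import synthetic
from dermseg.wavelets import dwt2_forward, feature_image

image, mask = synthetic.generate(synthetic.LesionSpec(noise_sigma=10.0, seed=3))
red = image[..., 0]

decomp = dwt2_forward(red, family="db4", J=1)
s = decomp.scales[0]
for name, band in [("A", s.A), ("D_h", s.D_h), ("D_v", s.D_v), ("D_d", s.D_d)]:
    print(f"subband {name:3s}: shape {band.shape}, energy {float((band**2).sum()):.3e}")

for mode in ("approximation", "magnitude"):
    feat = feature_image(red, family="db4", J=1, mode=mode)
    inside, outside = feat[mask], feat[~mask]
    sep = abs(inside.mean() - outside.mean()) / np.sqrt(inside.var() + outside.var())
    print(f"{mode:14s} feature: lesion/skin separation d' = {sep:.2f}")
print("\nThe approximation concentrates the intensity contrast (large d'),")
print("which is why it is the default clustering feature.")
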