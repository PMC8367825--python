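"""Render a tissue phantom and recover its chromophore maps.

A phantom scene embeds an elliptical lesion whose hotspot R610/R545 ratio
is set analytically; the forward model produces the four-band capture and
the two-chromophore inversion recovers the HbO2/Hb concentration maps.
"""

import numpy as np

from oralmsi import Lesion, PhantomScene, forward_reflectance, invert_chromophores

scene = PhantomScene(
    width=96,
    height=96,
    lesions=[Lesion(center=(48, 48), axes=(18, 14), grade="OPML", target_ratio=3.0)],
    seed=11,
)
capture, truth = forward_reflectance(scene)
maps = invert_chromophores(capture)

ok = ~capture.saturation_mask
err_hbo2 = np.abs(maps.c_hbo2 - truth.c_hbo2)[ok].max()
err_hb = np.abs(maps.c_hb - truth.c_hb)[ok].max()

print(f"lesion-core expected ratio : {truth.expected_ratio_map[48, 48]:.4f}")
print(f"max |C_HbO2 error| (mM)    : {err_hbo2:.2e}")
print(f"max |C_Hb   error| (mM)    : {err_hb:.2e}")
print("The noise-free inversion is exact to floating-point precision, so any")
print("disagreement on real captures comes from noise, saturation or model bias.")
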