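"""Score a lesion with the 5x5 hotspot rule and pick a healthy reference.

The lesion score is the mean R610/R545 over the 5x5 window centred on the
brightest valid in-ROI pixel; the healthy reference is the mean over a
clinician-drawn (or automatically suggested) normal patch.
"""

from oralmsi import (
    Lesion,
    PhantomScene,
    RegionOfInterest,
    SpectralBand,
    compute_ratio_map,
    forward_reflectance,
    healthy_reference,
    score_lesion,
    suggest_healthy_roi,
)

scene = PhantomScene(
    width=64,
    height=64,
    lesions=[Lesion(center=(24, 24), axes=(12, 10), grade="OPML", target_ratio=3.0)],
    seed=9,
)
capture, _ = forward_reflectance(scene)
rm = compute_ratio_map(capture, SpectralBand.R610, SpectralBand.R545)

lesion_roi = RegionOfInterest("lesion", ((10, 12), (38, 12), (38, 36), (10, 36)))
result = score_lesion(rm, lesion_roi)
print(f"hotspot pixel  : {result.hotspot}")
print(f"lesion score   : {result.score:.3f}  (5x5 mean at the hotspot)")

auto_roi = suggest_healthy_roi(rm, lesion_roi, window_size=7)
ref = healthy_reference(rm, auto_roi)
print(f"healthy ref    : {ref:.3f}  (auto-suggested {auto_roi.label!r} patch)")
print("The score averages over the lesion's edge taper, so it sits between")
print("the healthy background ratio and the lesion-core target of 3.0.")
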