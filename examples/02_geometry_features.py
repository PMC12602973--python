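"""Compute the tumor geometry features P, L, S from raw measurements.

For a lung spanning 30 cm cranio-caudally with the PTV-C center 11.7 cm
below the superior lung edge, a 23.4 cm in-lung PTV-C length and a
452.79 cm³ in-lung volume, the features evaluate to P = 0.39, L = 0.78 and
S = 19.35 cm² — the characteristic magnitudes of a mid-esophageal tumor.
"""

from dvhpredict import TumorLungGeometry, extract_features

geometry = TumorLungGeometry(
    lung_sup=0.0,  # superior lung edge (axis increases downward)
    lung_inf=30.0,  # inferior lung edge -> lung length 30 cm
    ptv_length_in_lung=23.4,
    ptv_volume_in_lung=452.79,
    ptv_center=11.7,
)
p, l, s = extract_features(geometry)
print(f"relative position      P = {p:.2f}   (center offset / lung length)")
print(f"relative length        L = {l:.2f}   (PTV-C length / lung length)")
print(f"axial cross-section    S = {s:.2f} cm^2 (PTV-C volume / length)")
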