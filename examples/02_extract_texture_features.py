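"""Extract the 23-feature radiomics vector from one masked phantom.

The vector couples mask morphology (area, perimeter, centroid, shape) with
first-order intensity statistics, 13 co-occurrence (Haralick) statistics,
local-binary-pattern histogram summaries and a SIFT keypoint count.
"""

from echopanc import default_spec, extract_features, generate_phantom

image, mask, label = generate_phantom(default_spec("DM", seed=11))
fv = extract_features(image, mask)
print(f"class = {label}, mask pixels = {mask.count}")
for name, value in fv.as_dict().items():
    print(f"  {name:28s} {value:10.4f}")
# Entropies are in bits; area/perimeter in mm^2/mm; centroids in cm from the
# image origin (centroid_y is the depth below the dermis); ASM, IDM and LBP
# energy lie in (0, 1] with 1 = perfectly uniform texture.
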