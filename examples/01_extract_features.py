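"""Extract the 27 G-M features of one nodule contour and select the 11.

Builds a smooth oval (benign-like) and a taller-than-wide spiculated
contour (malignant-like), extracts the full feature vector from each and
prints the clinically selected subset side by side.  Low solidity /
compactness flag irregular margins; aspect ratio above 1 flags the
taller-than-wide shape, both classic ultrasound malignancy signs.
"""

from gmnodule import extract_feature_vector, select_significant
from gmnodule.synthetic import ShapeSpec, generate_shape

benign_spec = ShapeSpec(
    class_label=0, base_semi_axes=(50.0, 32.0), rotation_deg=5.0, seed=21
)
malignant_spec = ShapeSpec(
    class_label=1,
    base_semi_axes=(34.0, 46.0),
    spicule_amplitude=0.15,
    spicule_count=10,
    lobulation_amplitude=0.05,
    seed=21,
)

vectors = {}
for name, spec in [("benign-like", benign_spec), ("malignant-like", malignant_spec)]:
    _, contour = generate_shape(spec)
    fv = extract_feature_vector(contour)
    vectors[name] = fv
    print(f"{name}: {len(fv)} features extracted, "
          f"{len(select_significant(fv))} selected")

print(f"\n{'feature':<20}{'benign-like':>14}{'malignant-like':>16}")
for feat in select_significant(vectors["benign-like"]):
    b = vectors["benign-like"][feat]
    m = vectors["malignant-like"][feat]
    print(f"{feat:<20}{b:>14.3f}{m:>16.3f}")

print(
    "\nThe malignant-like nodule shows lower solidity (ragged margin) and an\n"
    "aspect ratio above 1 (taller than wide); the benign-like oval is the\n"
    "opposite on both."
)
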