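# gmnodule

Geometric and morphological (G-M) shape analysis of thyroid-nodule
contours in ultrasound images, for benign/malignant decision support.

Radiologists grade thyroid nodules on ultrasound with TIRADS (Thyroid
Imaging Reporting and Data System), which scores visual attributes —
shape, size, margin irregularity, orientation — with substantial
inter-observer variability. This package quantifies those visual
attributes: given an expert-drawn nodule boundary (a closed polygon in
pixel coordinates, as found in DDTI-style XML annotations, or traced
from a binary mask), it extracts **27 geometric and morphological
features**, applies a fixed clinically chosen **11-feature TIRADS-aligned
selection**, balances imbalanced cohorts by seeded flip/rotate/blur
**augmentation**, and classifies nodules with a **400-tree entropy random
forest** on a stratified 70–30 split, reporting accuracy, sensitivity and
specificity. A seeded synthetic-shape generator emulates the two
phenotypes (smooth wider-than-tall ovals vs. taller-than-wide spiculated
contours) so the entire pipeline runs and is tested without any image
download.

## The features

With object area $A_n$, perimeter $P_n$ (Euclidean arc length), convex
hull area $A_c$ and perimeter $P_c$, major/minor axis lengths
$L_{MA}, L_{ma}$ (farthest border-point pair; longest chord perpendicular
to it), minimum-area rectangle $A_r$, and axis-aligned width $W$ / depth
$D$, the core descriptors are

- convexity $= P_c/P_n$, solidity $= A_n/A_c$ — margin irregularity;
- compactness $= 4\pi A_n/P_n^2$, roundness $= 4\pi A_n/P_c^2$ — circularity;
- rectangularity $= A_n/A_r$, elongation $= L_{ma}/L_{MA}$,
  eccentricity $= L_{ma}/L_{MA}$, axis ratio $= L_{MA}/L_{ma}$;
- circular variance $\sigma_R/\mu_R$ and elliptic variance
  $\sigma'_R/\mu'_R$ of the (Mahalanobis-normalized) centroid-to-boundary
  distances;
- aspect ratio $= D/W$ — the taller-than-wide malignancy sign;
- AP ratio $= A_n/P_n$, and the perimeter ratios/differences against a
  related ellipse (semi-axes $L_{MA}/2, L_{ma}/2$, Ramanujan-II
  perimeter) and an equal-area circle (TEP/TCP features).

The fixed 11-feature selection is: solidity, orientation, roundness,
major/minor axis length, bounding box ($L_{MA} \cdot L_{ma}$), convex
area, area, perimeter, aspect ratio, AP ratio.

## Worked example

```python
from gmnodule import extract_feature_vector, select_significant
from gmnodule.synthetic import ShapeSpec, generate_shape

_, contour = generate_shape(ShapeSpec(
    class_label=1, base_semi_axes=(34.0, 46.0),
    spicule_amplitude=0.15, spicule_count=10,
    lobulation_amplitude=0.05, seed=21,
))
fv = extract_feature_vector(contour)
print(len(fv))                       # 27
sel = select_significant(fv)         # the 11 TIRADS-aligned features
print(round(sel["solidity"], 3))     # 0.894
print(round(sel["aspect_ratio"], 3)) # 1.349
```

The malignant-like contour scores solidity 0.894 (ragged margin erodes
the area relative to its convex hull) and aspect ratio 1.349 (taller
than wide); a smooth benign-like oval scores ~1.0 and ~0.65 on the same
features. Longer narrative walkthroughs — cohort generation, balancing
a 17/82 cohort to 1594 + 1594 = 3188 rows, and the three-arm
random-forest comparison with a permutation control — live in
`examples/`; each prints the numbers it computes and what they mean.

There is also a thin CLI over the same API:

```bash
gmnodule simulate --n-per-class 100 --seed 7 --out-dir cohort/
gmnodule extract  --in cohort/syn-b0000.xml --out features.csv --select tirads11
gmnodule augment  --manifest-dir cohort/ --target-per-class 1594 --seed 5 --out balanced.csv
gmnodule train    --table balanced.csv --arm tirads11 --seed 7 --report report.json
```

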