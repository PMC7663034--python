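# Methods

This note records the model choices, conventions, numerical decisions
and known limitations behind `gmnodule`. Everything empirical stated
here is computed by the test suite or `scripts/acceptance.py`.

## Input model

The unit of analysis is a closed nodule boundary (`NoduleContour`): an
ordered list of (x, y) pixel coordinates, implicitly closed, in a
0-based x-right / y-down image frame. Boundaries arrive either as
polygon annotations (DDTI-style XML, where each `<mark><svg>` holds a
JSON array of point lists and `<tirads>` holds the clinical category)
or are traced from binary masks. Validation removes consecutive
duplicate points and an explicit closing point, and rejects boundaries
with fewer than 3 distinct points or zero shoelace area.

Contours traced from masks fill interior holes first (the ground truth
is a nodule *outline*) and follow the 0.5-level set of the indicator by
marching squares. Two numerical details matter:

- The binary indicator is lightly Gaussian-smoothed (sigma 0.8 px)
  before tracing. Tracing the raw indicator overestimates the perimeter
  of a digitized disk by ~5% (staircase bias), which propagates squared
  into compactness; with smoothing the disk perimeter is recovered to
  ~0.7% and the mask is still re-rasterized at Jaccard ≥ 0.98. Tiny
  objects that smoothing would erase fall back to the raw trace.
- Float inputs with fractional values are treated as coverage fields
  (anti-aliased rasterizations, interpolated rotations) and traced at
  the 0.5 level directly, which recovers the boundary with sub-pixel
  accuracy. `contour_to_mask(..., antialias=True)` produces such fields
  by 4×4 supersampling; binary rasterization marks a pixel foreground
  when its center lies inside the polygon (half-open rule), so pixel
  counts track polygon area without the ~perimeter/2 overcount of
  boundary-inclusive filling.

## Base geometry

Area is the shoelace area of the polygon; perimeter the Euclidean arc
length of its closed vertex chain. (Counting border pixels instead
would bias every perimeter-ratio feature, so the pixel-count reading of
"perimeter" is not used; the pixel-count notion of area survives as the
separate `filled_area` feature.) The convex hull is computed on the
polygon vertices (shapely), and the minimum-area enclosing rectangle is
the rotating-calipers optimum of the hull.

The major axis is the farthest pair among border points — literally the
longest line between any two boundary pixels. To realize that
border-pixel semantics for arbitrarily sparse polygon annotations (a
4-vertex rectangle has no vertex pair perpendicular to its diagonal),
the boundary is first resampled at uniform arc-length spacing (default
0.5 px, capped at 2500 points to keep the O(N²) searches tractable).
The same resampled border feeds the minor-axis search and the radial
statistics, which makes every feature independent of how many vertices
the annotator clicked. The sub-pixel default spacing keeps the
tolerance-band chord search stable: under mirroring and 90° rotations
the chord-based features move by ≲ 0.2%, versus ~1% at 1 px spacing.

The minor axis is the longest boundary-to-boundary chord perpendicular
to the major axis within ±2.0° (configurable); a projection-width
alternative (`minor_axis.mode = projection`) is exposed. Ties in both
searches break toward the lexicographically smallest endpoint pair, so
results are deterministic. Orientation is the major-axis angle after
conversion to a y-up mathematical frame, in degrees in (−90, 90].

Two distinct box notions coexist deliberately: elongation uses the
major-axis-oriented box (so it equals L_ma/L_MA), while rectangularity
uses the true minimum-area rectangle; the `bounding_box` feature itself
is the product L_MA · L_ma.

## Reference shapes

The perimeter-ratio features need a "related ellipse" and a "relevant
circle", neither of which has a canonical construction. The defaults
chosen here are dimensionally consistent and disk-neutral — both ratios
are exactly 1 for a disk:

- related ellipse: semi-axes L_MA/2 and L_ma/2, perimeter by the
  Ramanujan-II approximation (relative error < 1e-6 up to aspect ~5;
  verified against numeric arc-length integration to 0.1% for aspect
  ratios ≤ 4). A second-moment fit (`tep.reference = moments_ellipse`)
  is available.
- relevant circle: the equal-area circle, perimeter 2√(πA_n). A
  major-axis-diameter circle (`tcp.reference = major_diameter`) is
  available. Under the equal-area default, tcp_ratio ≡ compactness^(−1/2)
  exactly, one of the identities the suite checks at 1e-9.

## The 27 features

The registry in `features.py` lists all 27 with formula and units.
Three inventory conventions: "convex hull" is exported as the hull
vertex count (a polygon has no single scalar), "centroid" as one named
feature holding the (c_x, c_y) pair (flattened to two columns in
tables), and "bounding box" as the area L_MA · L_ma. Circular variance
is the coefficient of variation σ_R/μ_R of centroid-to-boundary
distances (not the squared form found elsewhere); elliptic variance is
the same statistic after Mahalanobis normalization by the covariance of
the centered boundary, d'_i = √(v_iᵀ C⁻¹ v_i), which is the reading
consistent with fitting an oval. Population (biased) standard
deviations are used. Aspect ratio is depth/width from axis-aligned
image extents, so values > 1 mean taller-than-wide in the clinical
sense; orientation is reported in degrees.

Exact identities that hold by construction and are enforced at 1e-9
relative on 200 random shapes: compactness = roundness · convexity²,
tcp_ratio = compactness^(−1/2), eccentricity · axis_ratio = 1,
ap_ratio · perimeter = area, bounding_box = L_MA · L_ma.

The 11-feature selection is a fixed clinical choice, not learned; the
complementary 16 ("discounted") and the full 27 ("global") are exposed
as experiment arms.

## Augmentation

Class balancing retains every original nodule and generates the
remainder by cycling over each class's originals with independent
stochastic draws: horizontal/vertical flips (p = 0.5 each), continuous
rotation about the image center (p = 0.5, U(−25°, 25°), canvas re-fit
so the nodule is never cropped), and Gaussian blur (p = 0.5,
σ ∈ U(0.5, 2.0) px). Geometric operations transform image and contour
identically; blur touches pixels only. All draws come from one seeded
generator: identical inputs, config and seed give byte-identical
cohorts, and each augmented row records its source case and op log.

Because features derive from the contour, blur-only draws duplicate
their source's feature row exactly. That duplication is kept by default
(it mirrors the augment-then-extract procedure the pipeline models) and
can be removed with `drop_feature_duplicates`. Feature tables written
from augmented cohorts carry the *source* case id, so a group-aware
split can keep augmented siblings on one side and measure the leakage
the default split incurs.

Consistency between the two representations is verified by comparing
features of the transformed contour against features re-traced from the
transformed raster: with anti-aliased rasterization every dimensionless
feature agrees within 2%. Binary rasterization has an inherent ~1%
staircase perimeter floor, which is a resolution limit of the raster,
not of the transform.

## Classification

A scikit-learn random forest with 400 trees, entropy criterion and
bootstrap aggregation, on a stratified 70–30 hold-out (test size
round(0.3 n), per-class counts by largest remainder). Splits, fits and
reports are deterministic given seeds. Metrics are accuracy,
sensitivity (TP rate, positive = malignant) and specificity (TN rate);
a metric whose denominator is empty is reported as NaN with a warning,
never silently zero. Group-aware splitting (off by default) assigns
whole source-case groups to one side.

## Synthetic cohort

The generator produces boundary geometry only — no ultrasound texture,
speckle, or intensity information — as a radial perturbation of an
ellipse: r(θ) = r_ellipse(θ) · (1 + lob · sin(3θ + φ) + spic · s(θ)),
with s(θ) seeded band-limited noise peaking at the requested spicule
count and normalized to unit amplitude. r > 0 keeps the curve
star-shaped, hence simple; if the modulation would reach zero it is
clamped with a warning.

Class defaults encode the TIRADS attributes: benign — horizontal
semi-axis 35–60 px, flatness b/a ∈ U(0.55, 0.9) (wider than tall),
near-horizontal rotation, spicule amplitude ≤ 0.03; malignant —
depth/width ∈ U(1.05, 1.5) (taller than wide), spicule amplitude
U(0.08, 0.2), lobulation U(0.03, 0.08). With these effect sizes the
class-conditional distributions of the selected features separate
almost completely (mean solidity gap > 0.05; aspect-ratio means on
opposite sides of 1), which is verified by Monte-Carlo in the tests
rather than assumed. Cohort sizes used in the checked experiments: 200
or 400 per class for classification, 17 benign / 82 malignant for the
imbalanced-augmentation scenario grown to 1594 per class (3188 rows).

Passing tests on this cohort demonstrate that the pipeline measures and
exploits contour geometry correctly; they do not demonstrate clinical
performance. Real expert contours carry annotation noise, scanner- and
operator-dependent habits, and class overlap that the generator does
not model, and real classification also depends on texture features
that are outside scope here.

## Known limitations

- Near-perfect accuracy on the synthetic cohort reflects the
  generator's deliberately separable effect sizes, not expected
  clinical performance.
- The augment-then-split default means augmented siblings of one nodule
  can appear on both sides of the split; the group-aware option exists
  precisely to quantify that leakage.
- Sub-pixel boundary structure (spicule amplitudes ≲ 1 px) is not
  preserved by rasterization; variance-type features of near-smooth
  shapes are ill-conditioned in relative terms.
- Whether a given annotation's perimeter was originally measured as
  arc length or pixel count cannot be recovered from the data; this
  package exports arc length.
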