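# Methods

## Problem and model

Diabetic retinopathy (DR) is graded on the international five-level scale —
0 No DR, 1 Mild, 2 Moderate, 3 Severe, 4 Proliferate — from the lesions
visible on a fundus photograph: hemorrhages (HE), hard exudates (EX), soft
"cotton-wool" exudates (SE), microaneurysms (AN) and new vessels (NV).
`drgrade` starts where a lesion detector or a human annotator stops: each
lesion is a typed simple polygon in pixel coordinates, and an image is
summarised by nine attributes

- four **area ratios** `R_HE, R_EX, R_SE, R_NV` — the summed polygon area of
  a type divided by the retinal area, and
- five **counts** `N_HE, N_EX, N_SE, N_AN, N_NV`.

Aneurysms contribute a count only: their individual areas are a few pixels,
so an area ratio would be numerically meaningless.

Polygon areas use the shoelace formula
`S = |Σ_j (x_j·y_{j+1} − y_j·x_{j+1})| / 2` with the last vertex wrapping to
the first.  The formula is applied as written to whatever the annotation
contains; self-intersecting outlines trigger no repair, only a warning,
because annotation polygons are drawn simple in practice and no principled
repair exists.  Overlapping polygons of the same type are summed naively —
the ratio definition is a plain sum over instances, so shared area counts
once per instance; this is documented rather than "fixed" because whether a
double-annotated region is one lesion or two is annotation policy.

The **retina is modelled as a perfect disk** whose radius is half the width
of the image after cropping to the retina, `S_retina = (W/2)² π`.  This
keeps the ratio well defined for photographs whose top and bottom retinal
caps are cut off (a common camera artifact): clipping is vertical, so the
width still spans the full disk diameter.  Ratios rather than absolute areas
make features comparable across source resolutions.  Ratios are not clamped
at 1; a value above 1 (polygon outside the disk model) warns.

Coordinates are continuous, 0-based, x rightward, y downward; no pixel-grid
rounding is applied anywhere in quantification.

## Grading rules

Grading is a first-match scan over an ordered list of conjunctive threshold
rules.  The shipped rule set (`data/dr_severity_rules_v1.json`) has nine
rules over `R_SE` (thresholds 0.111, 0.18, 0.342), `R_HE` (0.052, 0.171,
0.343), `N_SE` (0 vs 1..15) and `N_NV` (0 vs 1..3); each rule carries a
confidence — the training-leaf majority fraction, in percent — that is
reported verbatim at inference, never recomputed.  Boundary semantics are
exactly as stated: `=<` is ≤, `>` strict, `>=` ≥.  One redundancy is kept
deliberately: the Severe hemorrhage rule pairs `R_HE >= 0.052` with
`R_HE > 0.171`, which makes the first bound inert; it is preserved because
the rule set is a published artifact, not ours to tidy.

`audit_ruleset` treats each rule as a box (a product of half-open intervals
over the nine feature axes) and proves by interval intersection that the
nine rules are pairwise mutually exclusive.  Coverage is decided on the
atomic decomposition of the referenced axes (the rules' own bounds cut each
axis into atoms; a rule either fully contains or fully misses an atomic
box), and maximal uncovered boxes are reported by greedy atom expansion.
For the shipped set the uncovered space is exactly
`{R_SE ≤ 0.18, R_HE ≤ 0.052, N_SE > 15}` and `{R_SE > 0.18, N_NV > 3}` —
both artifacts of the bracketed count ranges in the printed rules.

Because more lesions cannot plausibly lower severity, the default fallback
for uncovered vectors (`widen_ranges`) relaxes integer ranges to their lower
bounds (`N_SE ∈ [1..15]` → `N_SE ≥ 1`, `N_NV ∈ [1..3]` → `N_NV ≥ 1`) and
flags `fallback_used`.  `error` and `nearest_rule` are selectable; the
nearest-rule distance normalizes ratio misses by a 0.5 span and count misses
by a 15-lesion span so the two kinds of predicate are commensurable.

Explanations render each predicate as a clause — feature long name,
comparator in words, ratio thresholds as percentages — joined by "and" and
closed with the severity statement, e.g. *"If the ratio of soft exudate
lesions is less than or equal 18% and the ratio of hemorrhage lesions is
greater than 5.2% and the ratio of hemorrhage lesions is less than or equal
17.1%, the severity is moderate."*

## CART learner

The tree learner that re-derives such rule sets from labeled tables is
written from scratch (scikit-learn appears only as a cross-check in the test
suite): Gini impurity `1 − Σ p_k²`, binary axis-aligned splits, exhaustive
search over midpoints of consecutive distinct values per feature (tables
here are thousands of rows, so no quantile subsampling is needed).  Ties
break toward the lowest feature index, then the lowest threshold, making
training deterministic for a fixed table; the `seed` field of `CartConfig`
exists for interface symmetry and is unused by the exact search.
Pre-pruning only (`max_depth` 12, `min_samples_leaf` 1,
`min_impurity_decrease` 0 by default); no cost-complexity pruning, surrogate
splits, missing values or categorical features.  Count features are split as
numerics; when an extracted root-to-leaf path bounds a count on both sides,
the pair is rendered as an integer range to match the shipped rules' style.

Rule extraction emits one rule per leaf (path predicates merged to tightest
bounds, majority class, confidence = 100·max_k count_k / Σ count_k,
**training-set** leaf fractions — whether published confidences of this kind
are cross-validated is generally unstated, so the simplest defensible choice
is made and named).  Since leaves partition the feature space, the extracted
set is exhaustive and exclusive, and first-match classification over it
reproduces tree traversal exactly (asserted on 10⁴ random probes).

## Synthetic data

`sample_features(severity, n)` draws vectors uniformly inside the chosen
severity's rule boxes (one box per rule, chosen uniformly), with every ratio
at distance ≥ `margin` (default 0.01) from **every** rule threshold, and
integer features strictly inside their printed ranges.  Decisions the rules
leave open, fixed once here:

- Unbounded intervals (`R_SE > 0.342`, `R_HE > 0.171`, `R_HE > 0.343`) are
  sampled in a band of width 0.05 above `threshold + margin`.  The band
  keeps per-image total lesion budgets below ~0.76 of the disk area, the
  most a non-overlapping packing can honour.
- A present lesion type contributes ratio ≥ 0.003 (anything smaller is not
  drawable as a sensible polygon); zero count ⇔ zero ratio, always.
- Unreferenced features take class-plausible values: `R_EX` ∈ [0.002, 0.015]
  (zero with probability 0.3), `R_NV` ∈ [0.002, 0.01] when `N_NV ≥ 1`,
  hemorrhage count grows with its ratio, and `N_AN` ranges rise with
  severity ((0–2) for No DR up to (3–12) for Proliferate).  None of these
  affect the assigned grade.
- Within-class distributions of real data are unknown; uniform-in-region
  sampling is a declared stand-in, not an estimate.  Consequently, passing
  recovery tests show the learner recovers **rule-consistent structure**,
  not that it would match clinician behavior on real images.

`render_fundus` packs one polygon per lesion instance into the retinal disk
using a squarified treemap in `(θ, u = r²)` coordinates — area in that plane
is proportional to image-plane area, so annular-sector cells of near-unit
aspect ratio can be allotted per instance (cell area = lesion area / 0.8).
Each polygon traces its cell boundary (8–16 vertices, 3 % inset), jitters
vertices toward the cell centroid, and is scaled about the centroid to the
**exact** target area, so quantifying the returned annotation reproduces the
requested ratios to float precision (the 2 % contract in the tests is
generous).  Aneurysms render as 5–25 px² blobs; vessel-like random-walk
curves are purely cosmetic.  Vertical clipping (as in cameras that cut the
retinal caps) is applied to ~30 % of generated images when the lesion budget
fits the reduced safe disk.  Requested budgets beyond the packable capacity
raise `InfeasiblePackingError`.

Generated datasets are balanced by construction (equal `n_per_class`),
mirroring the balanced-training-set design that grading rule sets of this
kind assume, and are byte-reproducible for a fixed seed.

## Preprocessing

`crop_to_retina` binarizes the ITU-R 601 grayscale at a fixed default
threshold of 10/255 (the sources of such pipelines state binarization but no
threshold; 10 separates the retinal disk from sensor-black reliably) and
crops to the foreground bounding box; idempotent to ±1 px.  `resize_square`
is bilinear to 1024×1024 by default.  `enhance_contrast` is CLAHE on the
YCbCr luma, `clip_limit` 0.02 (clip fraction in (0, 1]) over an 8×8 tile
grid; constant images are returned unchanged since there is no contrast to
redistribute.  `green_channel` returns the G plane exactly.  `augment`
applies horizontal flip, rotation (black corner fill, matching the fundus
background), contrast scaling about the image mean and brightness offsets,
clipped to [0, 255], with ranged parameters drawn deterministically from a
seed.  All ops are pure.

Out of scope by design: lesion detection from pixels (the input contract is
polygons), vessel-segmentation autoencoders and Mask R-CNN detectors (their
value is trained weights on clinical data), RLE mask decoding, per-patient
two-eye aggregation, and probabilistic recalibration of rule confidences.

## Problem sizes used in the checks

The test suite trains the tree on 5,000 sampled vectors (1,000 per class,
margin 0.01), evaluates on 1,000 held-out vectors, probes rule/tree
equivalence on 10⁴ random vectors, audits coverage with a 10⁵-point
vectorized probe, and round-trips 50 rendered images at 512 px (the packing
geometry is scale-free; 512 px keeps the suite fast).  The whole suite runs
in well under a minute on one CPU.
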