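# Methods

## The classification model

The workflow assumes that a segmentation front-end (any model producing a
usable nucleus mask) has already reduced an H&E tile to a 2-D mask. All
downstream decisions are made from per-object geometry alone.

**Connected components.** Binary masks are labeled with 8-connectivity so
that thin diagonal bridges do not split an object. Labels are assigned in
raster-scan order of each component's first pixel, which makes all outputs
deterministic. Instance masks from true instance-segmentation models skip
this step; their labels are relabeled onto a contiguous 1..n range.

**Morphometry.** All geometry uses pixel centers at integer coordinates.
For an object with pixel area A:

- *solidity ratio* r1 = A / A_hull, where A_hull counts pixels whose
  centers lie inside or on the convex hull — both ratios therefore live on
  the same pixel-count footing;
- *circle ratio* r2 = A / (π (F/2)²), where F is the maximum Euclidean
  distance between centers of border pixels (pixels with at least one
  non-object 4-neighbor). F is computed on the convex hull of the border
  points, which is exact for the point-set diameter;
- *circularity* c = (r1 + r2)/2. A rasterized disk scores ≈ 1 (0.991 at
  radius 40); an axis-aligned square scores (1 + 2/π)/2 ≈ 0.82; elongated
  multi-nucleus clumps score lower.
- *equivalent diameter* d = 2√(A/π)·s µm, with s the pixel size
  (default 0.25 µm/px). The diameter of an irregular object is deliberately
  defined through its area: it is well defined for any shape, matches the
  area histograms used to characterize the size classes, and is robust to
  boundary noise. A maximum-Feret definition would systematically overstate
  elongated nuclei.

Single-pixel objects have no defined border diameter; they receive r2 = 1
by convention and are in practice removed by the area filter (a pixel at
0.25 µm/px is 0.0625 µm² ≪ 1 µm²). r2 can marginally exceed 1 on coarse
rasters and is not clamped, preserving the arithmetic identity
c = (r1 + r2)/2 exactly.

**Filtering.** Defaults: minimum area 1 µm², no upper area limit,
circularity strictly greater than 0.5. Checks run in a fixed order
(too_small, too_large, non_elliptical) so the recorded exclusion reason is
deterministic when several would apply. No upper area constant is invented:
oversized objects are instead excluded downstream when their size ratio
exceeds the top of the large band. The dropout rate is the excluded
fraction of all detected objects.

A consequence of the two-ratio definition worth stating plainly: a merged
*pair* of convex nuclei is not very non-circular. Two equal touching disks
score c ≈ 0.69–0.71 (r1 ≈ 0.88–0.90, r2 ≈ 0.50–0.52), and no pair of
ellipses with axis ratio ≤ 1.6 drops below ≈ 0.55; only elongated clumps of
several nuclei (roughly six collinear disks, or irregular clusters with
concavities) fall under 0.5. The 0.5 default therefore removes gross
clumps and fragments, not clean two-nucleus merges. The test suite asserts
the *computed* behavior of such dumbbells (kept at 0.5, excluded at a
stricter 0.75), and one acceptance check that expects pair-dropout to track
the merged fraction at the 0.5 default is left failing rather than
weakened, since it is unattainable under this shape score.

**Classification and vote.** ρ = d / r_ref with r_ref the species mean
diameter of small non-neoplastic lymphocytes (dog 4.14 µm, cat 4.17 µm).
Class intervals are half-open, [lower, upper), for small and intermediate
and closed at the top for large, so a ratio exactly on a shared bound
belongs to the upper class and ρ = large_upper is still classifiable.
Nuclei with ρ outside [small_lower, large_upper] abstain from the vote but
are counted in the report. Vote ties break toward the larger class — the
diagnostically conservative direction for grading — and set a tie flag. An
image with no voting nucleus raises an explicit error instead of returning
a default.

## Threshold grid search

Candidates are the Cartesian product of four discretized ranges (defaults:
small_lower 1.00–1.29, small_upper 1.18–1.24, intermediate_upper 1.35–1.51,
large_upper 2.00–2.59, all at step 0.01), restricted to strictly increasing
quadruples — the only combinations that form valid classifiers; on the
default grid this leaves 149,940 of 214,200 raw combinations. Grid values
are materialized as exact decimals at the step's precision so boundary
comparisons are platform-stable. Each candidate is scored by classifying
every measured diameter per image, taking the per-image majority (same tie
rule; an image with no classifiable measurement predicts "unclassifiable"
and counts against its true class), and macro-averaging F1 over the three
classes. Macro averaging is the stricter choice when classes are roughly
balanced, and the scorer is verified against scikit-learn's multiclass F1
to 1e-12 in the tests. The optimizer is exhaustive; among ties it returns
the first candidate in lexicographic enumeration order and reports all
ties. The full default grid on a 30-image set scores in well under a
minute.

## Evaluation metrics

Dice = 2|X∩Y|/(|X|+|Y|), defined as 1 for two empty masks. Object
detection uses one-to-one greedy matching by descending IoU with a 0.5
threshold — the community standard for nucleus detection scoring — and is
verified against exhaustive optimal assignment on small scenes; zero
denominators in precision/recall report 0 with a degenerate-case flag.
Confusion matrices (rows = truth) and accuracy = trace/total are computed
via scikit-learn with strict label validation.

## Synthetic data

`generate_scene` emulates the statistical skeleton of a segmented tile:
1024×1024 px at 0.25 µm/px, elliptical nuclei with axis ratio 1.0–1.6,
per-class equivalent-diameter bands equal to the default classification
bands times the canine reference, uniform within-band draws (uniform rather
than Gaussian so class membership is unambiguous in recovery tests), ≥ 2 px
separation between distinct labels, and sub-pixel jitter retried until the
rasterized area is within 5% of the drawn target (typically within 2%).
`merged_pair_fraction` renders that fraction of labels as two overlapping
ellipses joined end-to-end along their major axes — the most elongated, and
hence least circular, realistic pair geometry. Determinism is total: one
integer seed fixes the mask bit-for-bit.

`generate_measurement_set` emulates the optimization input: per image, one
consensus class and 20–60 diameters drawn from that class's band plus
optional Gaussian noise. The first two images per class are *boundary*
images whose diameters concentrate within 0.01×reference of one band edge.
This is an identifiability device: a per-image majority vote is insensitive
to small threshold shifts (moving a threshold into a band misclassifies
only the sliver of nuclei it crosses), so with purely uniform draws the F1
objective has a broad plateau of equally scoring candidates and no search
can pin the band edges. A boundary image's majority flips as soon as the
corresponding threshold crosses its edge, which pins the two interior
thresholds exactly and the two outer ones up to the tie rule's lexicographic
minimum — the band values themselves. With noise-free data the search then
recovers the generating thresholds exactly.

What the generator does **not** emulate: staining texture, scanner domain
shift, ragged segmentation boundaries, holes, fragments, or clusters of
three and more nuclei. Passing recovery tests therefore demonstrates the
correctness of the measurement → filter → classify → vote → optimize chain,
not segmentation robustness on real slides.

## Problem sizes and numerical choices

The default test and reproduction runs use 200 scenes of 50 objects for
end-to-end recovery, 30-image measurement sets for the full-grid search,
and 100 random blobs for the Feret oracle — sizes at which every check is
exercised meaningfully while the whole suite completes in a couple of
minutes. Circularity tolerances (disks within 0.05 of 1, squares within
0.03 of the analytic value at the tested sizes) absorb rasterization error
at radii ≥ 20 px. Masks are written 8-bit when ≤ 255 labels and 16-bit
otherwise; labels above 65,535 are rejected rather than truncated.

## Known limitations

- The shape filter cannot separate a clean two-nucleus merge from a single
  elliptical nucleus (see above); true instance segmentation front-ends are
  the intended mitigation.
- The reference diameter is species-specific and built in only for dog and
  cat; other species require a measured reference.
- The majority vote reports but does not model within-tile heterogeneity; a
  tile mixing two size populations yields a flagged, possibly unstable
  vote.
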