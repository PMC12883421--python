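# Methods

This note documents the models, parameter defaults, numerical choices
and limitations of `mpnmorph`. It is the reference for *why* the
pipeline is built the way it is; the README covers *how* to run it.

## Problem setting

Three Philadelphia-negative MPN subtypes — pre-PMF, PV and ET — differ
histologically in marrow cellularity and in megakaryocyte number and
nuclear morphology. The pipeline quantifies exactly those two axes from
pathologist-annotated ROIs and feeds them to a linear classifier. A
fourth group, MPN-NOS ("not otherwise specified"), consists of patients
whose findings fit no single subtype; the classifier's per-class scores
are used to propose a subtype for them.

## Automatic cellularity

Cellularity is the fraction of countable marrow area occupied by
nucleated cells:

    cellularity = A_nucleated / (A_nucleated + A_adipocyte)

Only nucleated cells and adipocytes enter the denominator; stroma and
empty intertrabecular space do not. Edge cases: with nuclear area but no
adipocyte area the value is 1; with neither, it is undefined and raised
as an error rather than silently zeroed.

### Step 1 — background calibration

Marrow fat dissolves during processing, so adipocyte ghosts have pixel
values close to the empty-slide background. Each ROI therefore carries
two polygon annotations, tissue boundaries and a pure-background patch;
the mean and SD of the background patch calibrate what "near
background" means for that slide.

### Step 2 — adipocyte detection

Tissue pixels within `max(2·bg_sd, 4)` grey levels of the background
mean are adipocyte candidates (the tolerance floor of 4 grey levels
covers noiseless backgrounds). Pixel noise pokes small holes in the
thresholded mask and scatters isolated specks; holes up to ~4 µm² are
filled and specks below the minimum size removed before splitting.
Touching candidates are split by a distance-transform watershed (peaks
of the Gaussian-smoothed distance map, minimum separation 6 µm). The
split labels are then regrown by label expansion — 50 expansion
iterations per pass, 5 passes — *constrained to candidate pixels*, so a
region's extent never outruns the intensity evidence; with clean masks
the expansion is a no-op, with fragmented ones it re-absorbs watershed
lines and fringe pixels. Finally, regions with circularity
(4πA/P²) < 0.3 or fewer than 5 px are discarded. An empty result is
legitimate (hypercellular marrow can contain no fat).

The unconstrained reading of "50 dilation iterations repeated 5 times"
would grow every region by 250 px regardless of image content, which
destroys the area ratio the whole measurement exists for; the
constrained form keeps the iteration structure as configuration while
the threshold mask bounds the geometry.

### Step 3 — nucleated-cell detection

The image is resampled to a 0.5 µm working pixel, inverted and scaled
to [0, 1] so nuclei are bright, and background-subtracted with a
grey-scale morphological **opening** using a disk of the 8 µm background
radius. Opening has the same contract as rolling-ball subtraction —
structures wider than the radius are flattened into the background —
and is substantially cheaper; the decomposed-disk footprint keeps it
exact enough for this purpose. An optional median filter (default
radius 0 = off) and a Gaussian blur of sigma 1.5 µm follow; pixels above
the 0.1 intensity threshold inside the tissue polygon form the nucleus
mask, and pixels whose local background estimate exceeds the maximum
background intensity (default 2.0 on the [0, 1] scale, i.e. a
pass-through) are rejected.

Two post-processing decisions matter numerically:

* **Half-maximum refinement.** Thresholding a Gaussian-smoothed image at
  a fixed low level inflates outlines: for a ~7 px-radius nucleus
  smoothed at sigma 3 px, the 0.1-threshold contour sits ~3 px outside
  the true edge, which would overestimate nuclear area by > 50% and bias
  cellularity upward. Each detected region is therefore tightened to
  the pixels above half of its own peak smoothed response; the
  half-maximum contour of a blurred step edge sits on the true edge, so
  the refined areas are approximately unbiased. This is the package's
  realisation of "the watershed algorithm was also applied to the
  binarized image to refine cell boundaries".
* **Selective splitting.** The watershed split is applied only to
  components whose refined area exceeds the 400 µm² single-cell
  maximum. Lobulated megakaryocyte nuclei below the gate therefore stay
  whole (and remain measurable as single high-caliper regions), while
  merged clumps above it are separated and their sub-gate pieces kept.
  Whether a > 400 µm² nucleus should survive as one region or as split
  lobes is genuinely ambiguous; this default keeps the printed area
  gate authoritative. A planted 600 µm² disc, for instance, is split or
  excluded but can never survive as a single region.

The 5 µm cell-expansion boundary is computed and attached to the result
(`cell_labels`) but unused downstream: all morphometry concerns the
nucleus, not the expanded cell.

## Morphometry

Per nucleus: area (pixel count × pixel area), perimeter, circularity
4πA/P² (capped at 1), ellipse-equivalent eccentricity √(1−(b/a)²) from
central second moments, and maximum caliper (Feret) diameter.

* **Perimeter** uses the Crofton projection estimator. The
  boundary-walk estimator with diagonal correction systematically
  overestimates smooth outlines (a rasterised disc of radius 50 px
  plateaus at circularity ≈ 0.91), whereas Crofton converges
  (≈ 0.99); since the circularity values feed interpretable features,
  the near-unbiased estimator is used. Circularity is capped at 1
  because the estimator can undershoot on few-pixel regions and no
  physical region is rounder than a disc.
* **Caliper** is the maximum pairwise distance over the convex hull of
  the pixel *corner* points (equal, by convexity, to the exhaustive
  all-pairs maximum, which the tests verify). Corners rather than
  centers make an n-pixel line measure n px, matching physical extent.
* **Megakaryocyte filter**: eccentricity > 0.8 AND caliper > 20 µm, both
  strict. The caliper threshold is read in µm — 20 µm matches
  megakaryocyte nuclear dimensions, and at the 0.5 µm working pixel no
  other unit is plausible. The filter is order-preserving and
  idempotent.
* **Cell density** (per ROI): megakaryocyte nuclear area / total nuclear
  area, dimensionless, invariant to uniform area rescaling.

## Per-patient features

Five statistics — mean, sample SD (n−1), moment skewness g1, excess
kurtosis g2, Shannon entropy — for each of area, perimeter and
circularity over the **megakaryocyte-filtered nuclei pooled across the
patient's ROIs** (a switch admits all nuclei), the same five statistics
over the per-ROI cell densities, and the nucleated-area-weighted
cellularity: 21 columns in a fixed, versioned order.

Conventions and degenerate cases: skewness/kurtosis use the biased
(population-moment) form and map to 0 when the SD is 0; entropy is
computed on an equal-width histogram between the sample min and max
with `min(10, n)` bins (3 bins for the 3 per-ROI densities) in natural
log units, 0 for constant samples. Aggregation inputs are sorted first
so the vector is bit-identical under ROI permutation. A patient with no
nucleus passing the megakaryocyte filter cannot be featurized and
raises a dedicated error rather than imputing.

The descriptive feature count has two published readings (3 features ×
5 statistics is announced as "12", and the total as "17", neither of
which matches 3×5 + 5 + 1 = 21). The package default is the full
21-column set; `feature_set="paper17"` drops the four entropy columns
(3 nuclear + density), the only reading that arrives at 17 = 3×4 + 4 +
1 and is consistent with "12" = 3×4. The ambiguity is surfaced as
configuration rather than resolved silently.

## Screening, classification, evaluation

* **Kruskal–Wallis screen** per feature across the three subtypes,
  tie-corrected H with the chi-square approximation; features with
  p < 0.05 are kept. Constant features get H = 0, p = 1. By default the
  screen runs once on the full labelled cohort before cross-validation,
  matching the study design; `nested_selection=True` repeats it inside
  each training fold so no test-fold observation influences the
  selected set (the tests verify this by recomputation). The default
  mirrors the published procedure; the nested flag exposes the
  leakage-free alternative.
* **Standardization** is column-wise z-scoring with training-set
  parameters (n−1 SD); zero-variance columns raise an error naming the
  column. Columns constant within a CV training fold are dropped for
  that fold (they carry no signal and cannot be scaled).
* **Linear SVM** (C = 1 by default, configurable; no tuning). Per-class
  scores are pairwise-coupling probability estimates, so each patient's
  three scores form a simplex — the form in which published NOS score
  rows are given. Class weighting is off by default. Training is
  deterministic under a fixed seed.
* **Cross-validation**: stratified 5-fold, repeated 5 times, one master
  seed; standardizer and SVM are refitted on each training fold. AUCs
  (per-class one-vs-rest, Mann–Whitney rank form with ties counting
  1/2, and their label-weighted sum) are averaged over all 25 folds;
  accuracy and the micro metrics are computed per repeat from the
  aggregated test predictions and then averaged.
* **Micro metrics**: sensitivity, specificity and precision from
  tp/fp/fn/tn summed over the three one-vs-rest confusions per round,
  means over rounds, then F1 = 2SP/(S+P) and G-mean. The G-mean
  default is the plain product S·Spec — the formula as published —
  with `gmean_sqrt=True` for the conventional √(S·Spec). Note that for
  single-label multiclass predictions Σfp = Σfn, so micro precision =
  micro sensitivity = accuracy identically (a property the tests assert
  exactly); the published micro-F1 of 0.50 alongside accuracy 0.60
  cannot both arise under this identity, so the formulas are
  implemented as stated and the tension is noted here rather than
  patched.
* **NOS assignment**: the model is refitted once on the full labelled
  cohort and each NOS patient assigned to the argmax of the score
  simplex, ties broken toward the *last* maximal class in the order
  (pre-PMF, PV, ET) — the rule that reproduces all 13 published
  assignments including the tied row.
* **Concordance**: against follow-up, NA and UNCHANGED entries are
  ineligible, "PMF" counts as pre-PMF, and matches are exact (4/8 = 50%
  on the published table). Against histology-at-biopsy the annotations
  often name two overlapping subtypes and no single matching rule
  reproduces the published 61.5%: accepting any mentioned subtype gives
  11/13, accepting only unambiguous single-subtype annotations gives
  7/13. Both policies are implemented; neither is presented as the
  published rule.
* **Cellularity agreement** uses the two-sample Kolmogorov–Smirnov test
  (asymptotic p), the mean absolute paired difference, and a histogram
  of |differences| in 0.1 bins over 0–0.4. Pathologist ranges resolve
  to their upper bound. The asymptotic p on small samples is
  conservative and the exact null distribution is discrete, so the
  calibration property tested is the operational one — null rejection
  rate ≈ alpha and mean p near 1/2 — not literal uniformity of p.

## Synthetic data

The generator exists so that every stage is testable against exact
ground truth. It emulates, per diagnostic class:

* **Cellularity** — clipped Gaussian (±3 SD, then clipped to
  [0.05, 0.95]) with the published per-class cohort parameters:
  0.55 ± 0.12 (pre-PMF), 0.67 ± 0.13 (PV), 0.65 ± 0.14 (ET). Only mean
  and SD are published; the clipped Gaussian is the minimal shape
  consistent with them.
* **Megakaryocyte nuclei** — unions of 2–5 overlapping discs ("lobes")
  along a jittered line. Lobe count follows the profile's lobulation
  parameter (pre-PMF 2 — bulbous/hypolobulated; PV 3; ET 4 —
  hyperlobulated), areas are Gaussian (pre-PMF 240 ± 50, PV 220 ± 45,
  ET 280 ± 60 µm²), and construction geometry is chosen so eccentricity
  and caliper clear the filter thresholds with margin; every planted
  nucleus is *measured* at build time and rejected if it would not pass
  (small nuclei are likewise verified to fail). These morphology
  defaults are package choices on histological plausibility — the
  source study publishes no megakaryocyte size/shape distributions.
* **Small nuclei** — discs of ~38 µm² (erythroid/myeloid scale);
  **adipocytes** — discs of radius 12–30 µm at background intensity
  (the final adipocyte may be trimmed below the range minimum to close
  the area budget exactly).
* **Rendering** — one 8-bit channel: background 232, stroma 195, nuclei
  70 (megakaryocytes 64), 0.3 µm blur, additive Gaussian noise (SD 2).
  The detection algorithm needs intensity contrast only, so no RGB/H&E
  colour model is simulated. Default field of view 224 µm at 0.25 µm/px
  (a 40× scan), with a 16 µm pure-background margin providing the
  calibration annotation.
* **Placement** — objects occupy 16% of the tissue area with a minimum
  4 µm gap, placed by rejection sampling with a bounded attempt budget;
  an unsatisfiable density raises a packing error. Area budgets are
  assigned so the mask-level cellularity tracks the drawn value to
  ~±0.01, and the stored `true_cellularity` is always recomputed from
  the masks exactly.

The direct feature-cohort generator maps each class profile to an
analytic 21-column mean vector (areas and densities from the profile;
perimeter via a lobulation-dependent shape factor; circularity as its
4πA/P² consequence; mild lobulation-dependent higher moments) and draws
patients from class-conditional Gaussians whose per-column SD is
`noise_scale` × the between-class spread of the means (floored at 5% of
the mean magnitude). `noise_scale=1` therefore means ≈1-SD class
separation on discriminative columns, and `noise_scale=0` reproduces the
class means exactly.

**What passing tests do and do not show.** The synthetic images have
non-touching cells, uniform stroma, no stain variation, no fibrosis
texture, no megakaryocyte clustering and no scanner artefacts, so
recovery there demonstrates correctness of the measurement chain, not
expected performance on real slides. Likewise the synthetic cohort's
near-perfect cross-validated AUC reflects its engineered separability;
the published cohort's AUC of ≈0.70 depends on data that is not
deposited and is reproduced here only as worked-example arithmetic.

## Problem sizes and tolerances

The test suite and the acceptance script use: 50 ROIs spanning
cellularity 0.4–0.8 (recovery within 0.05 required for ≥ 90%; observed
mean absolute error ≈ 0.01), 9 patients × 3 ROIs for the
megakaryocyte-filter F1 (threshold 0.9), 1,000 effect-free features for
the Kruskal–Wallis calibration (99% exact binomial band around 0.05),
a 19/30/39-patient feature cohort for 5×5-fold CV (weighted AUC ≥ 0.8;
label-permutation null within 0.5 ± 0.08), and 100+ random small
instances per statistic for the brute-force oracle comparisons. Image
tests use a reduced 150–160 µm field of view where full scale adds
nothing; Monte-Carlo cellularity means use 200 seeds (±0.02 band).

## Known limitations

* Touching or overlapping nucleated cells are split only above the
  400 µm² gate; densely packed real marrow would need marker-controlled
  watershed at the single-cell scale.
* The NOS stage refits a single model on all labelled patients; an
  ensemble over CV folds is a reasonable alternative that is not
  implemented.
* Colour deconvolution, stain normalisation, whole-slide tiling and
  fibrosis grading are out of scope.
* The histology-concordance matching rule is configurable because the
  published rate cannot be reproduced from the published table under
  any single rule; users must choose and report the policy.
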