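# Methods

## Problem and model

The package localizes the transition zone (TZ) of adhesion-related
small-bowel obstruction on abdominopelvic volumes by ranking sub-volumes
rather than segmenting. Three components interact:

1. a **patch classifier** — the abdominopelvic ROI is tiled into `k^3`
   patches and a 3D CNN scores each patch for "contains a TZ center";
2. a **spatial prior** — the per-patch probability that a scan's TZ
   center falls there, estimated as a per-patch relative frequency over
   the registered training annotations;
3. a **coupling rule** — the product of the two, read out as the curve of
   highlighted-volume fraction against the patch-level false-negative
   rate.

The statistical content of the coupling is naive-Bayes-like: treating the
classifier score as (proportional to) `P(signal | patch appearance)` and
the prior as `P(TZ in patch)`, their product re-ranks patches by joint
evidence. It can only help when location carries information, i.e. when
the TZ spatial distribution is concentrated — which it is: more than half
of TZs sit in the hypogastric region.

### Assumptions

* Annotation boxes carry no rotation information, so inter-scan
  registration is an axis-aligned affine fixed exactly by the two body
  ROIs (per-axis scale + translation). Anatomy is assumed roughly
  proportionate across subjects once the body bounding box is matched.
* A patch is "positive" iff it contains the **center** of an annotation
  box; a single-TZ scan therefore has exactly one positive patch out of
  `k^3`, and a closed-loop scan one or two.
* Patch priors are estimated per patch *index*: because every scan's ROI
  is tiled by the same `k^3` grid and the registration maps ROI corners
  onto corners, patch `(i, j, l)` corresponds across scans exactly.
* The nine abdominal regions are equal thirds of the ROI along z
  (cranio-caudal) and x (right-left), ignoring y. No annotation-free
  alternative exists; anatomical landmark-based regions are out of scope.
  Points exactly on a boundary go to the lower-index third, and the same
  convention applies to patch boundaries.

## Synthetic cohort

Clinical CT is replaced by phantoms so the full pipeline runs at desk
scale:

* **Body**: an ellipsoid of intensity 1 on a zero background, semi-axes
  defaulting to 90% of the volume half-extent; default volume 96x128x96
  voxels at 3 mm — a 0.3-scale version of a typical abdominopelvic crop
  (~300x400x300 mm) so all geometry stays spacing-aware.
* **TZ signature**: a bright (2.5) sphere abutting a dark (0.0) sphere,
  each of radius `tz_radius_mm` (default 15 mm), along a random axis —
  the dilated-upstream/collapsed-downstream caliber change reduced to its
  intensity essentials. The annotation box is the tight bound of the
  voxelized signature.
* **Spatial distribution**: signature centers are drawn per region from a
  categorical prior calibrated to the observed nine-region TZ frequencies
  (hypogastric 56.9%, right lumbar 14.7%, umbilical 13.1%, ..., printed
  values summing to 99.9 and renormalized), then uniformly within the
  region cell intersected with a margin-shrunk body (rejection sampling).
  Centers are additionally kept 2 voxels clear of region boundaries so
  the voxelized box center cannot drift across a region edge — a
  bookkeeping guarantee, not a distributional statement.
* **Cohort structure**: `closed_loop_prob` (default 0.2 — the source
  cohort reports no open/closed mix, so this is an explicit assumption)
  gives two TZs instead of one; patients contribute 1 to
  `scans_per_patient_max` (default 2) scans, emulating a cohort with
  repeat imaging; splits are patient-level 70/20/10.
* **Noise**: additive Gaussian, default sd 0.05 against a body/signature
  contrast of 1.0–1.5.

What the phantoms do **not** emulate: bowel anatomy and fluid levels,
Hounsfield calibration, scanner effects, anisotropic spacing, annotation
error, or any correlation between TZ appearance and location. Passing
tests on phantoms therefore demonstrates that the pipeline's machinery —
registration, prior estimation, training, coupling, evaluation — is
correct and that the coupling effect appears when location is
informative; it says nothing about clinical performance.

## Classifier

Four convolution blocks (two 3x3x3 convolutions each, ReLU then batch
normalization, then 2x2x2 max pooling) followed by two dense layers with
ReLU and 0.5 dropout and a sigmoid head. Channels double per block from
`base_channels`. The loss is balanced cross-entropy with
`w+ = N/2N+`, `w- = N/2N-` computed on the training patches (prevalence
is `1/k^3`–`2/k^3`, so unweighted training collapses to the majority
class). Positive patches are re-extracted every epoch under random
translation (uniform per axis in ±30 mm, spacing-aware) and window zoom
(uniform in 0.8–1.2). Augmentation may in principle move a TZ center out
of its patch; the stored label is preserved (the translation bound is
2 x tz_radius at defaults, so the signature remains at least partially in
view).

Since no deep-learning framework is available in the target environment,
the network is implemented directly: numpy layers with manual
backpropagation, the three convolution passes (forward, weight gradient,
input gradient) as numba-compiled kernels, Adam as optimizer. Gradients
are verified against finite differences in the test suite.

Training defaults: Adam at 1e-3, batch 16, up to 50 epochs, early
stopping on validation AUROC with patience 5 (patience 0 means exactly
one epoch). Inference disables dropout and uses batch-norm running
statistics. All randomness (init, shuffling, dropout, augmentation)
derives from explicit generator streams, so training histories are
bit-reproducible.

Defaults were sized for a single CPU: `base_channels=4`, dense (256, 64)
as the package default; the end-to-end acceptance runs use
`base_channels=2`, dense (64, 32) with 32-voxel patches — the smallest
configuration that separates the phantom task — and 10 training epochs.

## Evaluation

* **AUROC** by the Mann-Whitney pair-concordance statistic (ties ½), CI
  by percentile bootstrap over samples (2000 resamples by default,
  seeded); the implementation is property-tested against exhaustive
  pair counting.
* **Youden threshold**: lowest maximizer of sens + spec − 1 over midpoint
  candidates plus extremes, computed on validation; the lowest-threshold
  tie-break favors sensitivity, i.e. not missing TZs.
* **Precision** TP/(TP+FP) at a threshold; when no patch passes, the
  value is signaled as undefined (exception), never silently 0.
* **Volume-vs-FN curve**: one global threshold swept over the pooled test
  scores; per threshold, the FN rate is the fraction of true TZ patches
  not highlighted (closed-loop scans contribute two countable positives)
  and the volume fraction is the mean over scans of the highlighted patch
  fraction (patches are equal-volume up to one-voxel slabs, so patch
  counting and voxel counting agree to that resolution). Curve endpoints
  are pinned at (FN 0, volume 1) and (FN 1, volume 0).
* **Expected false positives**: with one true patch among `k^3`, wrongly
  highlighted patches at false-positive rate `p` follow
  Binomial(k^3 − 1, p); the package reports the mean `n·p` (e.g. 17.36 ≈
  17 of 124 at p = 0.14, k = 5).
* **Per-region AUROC** restricts the pooled patches to those whose grid
  centers fall in a region; single-class regions are flagged unavailable.
  (Summing scores within regions before ranking is a possible alternative
  reading; per-patch restriction is what is implemented.)

## Numerical choices and degenerate inputs

* Patch resampling uses corner-aligned trilinear interpolation
  (`linspace(lo, hi-1, side)` per axis), exact on affine intensity
  fields; intensities are rescaled to [0, 1] by the scan's body-mask
  1st/99th percentiles and clipped. A constant patch maps to zeros.
* Uneven partitions put remainder voxels in the lowest-index intervals;
  patch extents differ by at most one voxel per axis.
* The patch prior is floored at 1e-3 so no patch is permanently
  invisible after coupling; a hard zero would make any TZ there
  undetectable at every threshold.
* The prior floor, Youden tie-breaks, boundary-point conventions, and
  box-rounding (nearest-voxel corners when a registered float box indexes
  the reference grid) are each pinned by unit tests.
* Degenerate cases error loudly: empty body masks, zero-extent boxes,
  single-class label vectors, augmentation of negative samples,
  training splits missing a class.

## Problem sizes

Unit tests run on 48x64x48-voxel phantoms at 4 mm spacing with 6 mm
signatures; the end-to-end acceptance checks use a 150-patient cohort at
the default 96x128x96 / 3 mm geometry with 32-voxel patches and k = 3,
and a 10-patient cohort at 16-voxel patches for the bit-reproducibility
check. These sizes are the package's desk-scale study conditions; every
one of them is a config knob.

## Known limitations

* The coupling benefit at a fixed low FN tolerance is variance-sensitive
  at desk scale, and at k = 3 it can invert. The test split of a
  150-scan cohort holds only ~20 positive patches; roughly 15% of TZs
  fall in rare (low-prior) regions, and once the FN budget forces the
  coupled threshold low enough to recover them, every decent-prior patch
  lights up. Coupling pays off when the classifier produces many false
  positives for the prior to suppress — the regime of fine partitions
  (k = 5 gives 124 negative patches per scan and ~17 expected false
  positives at a 0.14 FP rate) — and can cost as much as it saves when
  k = 3 leaves few false positives per scan. On seeded desk-scale runs
  the coupled curve's volume at FN <= 10% lands within one
  patch-highlight of the raw curve's, on either side, depending on the
  cohort draw; k = 5 at full patch resolution is beyond a
  single-CPU-minutes budget, so the desk-scale suite demonstrates the
  machinery and the *conditional* nature of the benefit rather than a
  guaranteed volume reduction.
* The body-ROI extractor (threshold → closing → largest component) is a
  deterministic stand-in appropriate for body-on-air volumes; it is not
  an organ-aware abdominopelvic extractor.
* The affine registration cannot correct rotation or deformation; it is
  exactly as expressive as the bounding boxes that parameterize it.
* Regions are ROI-relative thirds, not landmark-defined anatomy.
* Phantom realism limits are listed above; no claim about clinical CT
  performance is made or tested.
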