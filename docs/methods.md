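# Methods

## Problem and scope

`cowgait` implements a desk-scale pipeline for grading dairy-cow
lameness (sound / mild / severe) from overhead RGB-D recordings.
Lameness alters posture and gait: the back arches (kyphosis), the head
nods, the trunk tilts, the spine sways, and the two body sides move
with unequal intensity.  The pipeline quantifies these manifestations
as six scalar features per walking sequence, screens them for genuine
discriminative power, and fuses the retained features into a three-way
severity classifier.  The farm recordings behind the published class
means are not publicly deposited, so the package ships a synthetic
generator whose sequences realise configurable feature targets; all
guarantees are stated and tested on those synthetic conditions.

## Depth preprocessing

Raw overhead depth frames (mm, `0` = void) pass through a fixed chain:

1. **Clip** to the closed interval [1200 mm, 2600 mm]; out-of-range
   pixels become void.  The boundaries are treated as inclusive — the
   stated range is read as a closed interval.
2. **Bilateral filter**, spatial sigma 5 px, range sigma 0.1 on depth
   normalised to [0, 1] over the clip span (i.e. 140 mm).  The spatial
   kernel is truncated at 2 sigma; voids are excluded from the kernel
   and stay void.
3. **3x3 masked median**, removing isolated outliers.
4. **Nearest-neighbour hole filling**: each void takes the value of
   its nearest valid pixel (Euclidean distance; exact ties broken by
   the lexicographically smallest (row, column) so results are
   reproducible).

Sequence screening rejects a sequence when any frame's void rate
inside the body region is >= 10%.  The stricter per-frame-maximum
reading was chosen over a per-sequence average; the threshold is a
config value.  Foreground segmentation keeps valid pixels more than
`min_height` (default 300 mm) above the floor plane (default 2500 mm,
consistent with a 3.2 m camera mount over standing cows) and retains
the largest connected component.  Grayscale export maps the clip span
linearly onto 0-255 with half-up rounding.

The chain is idempotent stage-by-stage except the denoising filters,
which are smoothing operators and therefore only approximately so.

## The six gait features

Let d(p, t) be the depth at keypoint p in frame t, looked up as the
median of the valid 3x3 neighbourhood around the rounded pixel (this
tolerates single-pixel sensor noise); heights are
h = (camera_height - d) / 10 in cm.

- **BC (1/cm)** — back curvature.  Per frame, withers, lumbar and
  sacral tuber are mapped to sagittal points (s_i, h_i), where s_i is
  the cumulative along-spine horizontal distance in cm.  The curvature
  of the circle through the three points is k = 4A/(abc) (A the
  triangle area, a, b, c the side lengths); collinear triples give 0.
  BC is the maximum over frames.  The sagittal plane was chosen
  because the feature quantifies kyphosis and its units are 1/cm of
  arc in the vertical plane; an overhead-plane variant would conflate
  lateral sway with arching.
- **MAI (unitless)** — movement asymmetry index.  Dense optical flow
  is computed between consecutive textured frames; the body mask is
  split into left/right halves by the sign of the cross product about
  the withers->lumbar axis (zero-cross pixels go left).  Flow
  magnitudes are accumulated over all frame pairs before the ratio
  MAI = |muL - muR| / (muL + muR), giving one index per sequence
  (per-frame averaging is available as an option).  The dense flow
  estimator is scikit-image's iterative Lucas-Kanade (`optical_flow_ilk`,
  window radius 4, 10 warps, Gaussian weighting); on band-limited
  translating texture it recovers a 2.5 px/frame motion with <0.1%
  bias.  MAI is reported absent when a sequence has no textured frames.
- **VOB (cm)** — vertical oscillation of the back: the largest
  temporal depth range among withers, lumbar and sacral tuber.
- **VOH (cm)** — vertical oscillation of the head: the temporal depth
  range at the poll.
- **TI (cm)** — trunk inclination: the largest |left - right| depth
  difference over frames, across the scapula pair and the tuber-coxae
  pair.
- **LSAS (cm)** — lateral sway amplitude of the spine: the largest
  horizontal peak-to-valley excursion among the scapula midpoint, the
  lumbar point and the sacral tuber (raw image abscissae, no drift
  detrending by default, matching the plain reading of the
  definition; a detrend option exists).

All features are nonnegative; MAI lies in [0, 1].  BC/VOB/VOH/TI are
invariant to in-plane rigid translation of the keypoints, LSAS to
travel-direction translation.

## Synthetic walking sequences

The generator is first-class, tested code: it defines the conditions
under which every downstream guarantee is verified.

- **Class targets.**  Per-class mean feature values are the published
  estimates (sound / mild / severe rows for BC, MAI, VOB, VOH, TI,
  LSAS).  Within-class spread is a truncated-at-zero (and at one for
  MAI) normal per feature with coefficient of variation 0.15 by
  default.  The sources publish class means only, so the noise model
  and its cv are package choices, flagged in the config; 0.15
  reproduces the qualitative between-class overlap of the published
  box plots.
- **Template.**  The eight keypoints sit on a fixed anatomical sketch
  (poll 30 cm ahead of the withers; scapulae and tuber coxae mirrored
  +-18 / +-16 cm about the spine; lumbar at mid-chord; chord 120 cm),
  scaled by 1.25 cm/px into a 160x96 frame, walking down the image.
  No template geometry is published; this layout is the package's own.
- **Signals.**  The static arch realises the BC target by raising the
  lumbar by the sag of a circular arc (sag solves
  d^2 - 2Rd + L^2/4 = 0 with R = 1/k).  Oscillations (VOB, VOH),
  left-right depth imbalance (TI) and lateral sway (LSAS) are sampled
  sinusoids at the stride frequency (1 Hz default, 30 fps, sway at
  half the stride rate) rescaled so the discrete samples attain the
  exact peak-to-peak target; that makes noise-free round-trips through
  the extractors exact to floating precision.  Depth is rendered as a
  floor plane (2500 mm), a body ellipse (1800 mm), and constant 5x5
  patches at each keypoint so the 3x3-median lookup returns the
  analytic value exactly.
- **Flow texture.**  Textured frames are a smooth checker plus
  band-limited speckle, periodic, translated by exact FFT phase shifts;
  the two image halves scroll at c(1 +- m) px/frame (c = 2 by default)
  so the analytic asymmetry equals the MAI target m.  Flow estimation
  and boundary smoothing bias the recovered MAI low by roughly 5-15%,
  which is why the flow round-trip tolerance is 30% while the
  depth/coordinate features carry 1e-6 tolerances.
- **What is not emulated.**  No photorealistic appearance, no camera
  distortion, no occlusions, no keypoint-detector errors, no
  correlated feature noise, and the walking speed is constant.
  Passing round-trips therefore certify the extractors' arithmetic and
  the pipeline's plumbing, not robustness to real farm imagery.

## Feature screening

Impurity-based importances are biased, so screening combines:

1. **Gini importance** from a random forest (500 trees by default,
   sqrt(d) features per split, unlimited depth; importances normalised
   to sum to one).
2. **Permutation null (PIMP)**: B = 50 label permutations, each with a
   fresh derived forest seed, giving a B x d null importance matrix.
3. **Right-tail p-value** with add-one smoothing,
   p = (1 + #{null >= observed}) / (1 + B); ties count against the
   observed value, and the smallest attainable p is 1/51.
4. **Benjamini-Hochberg** step-up adjustment; a feature is retained
   iff its adjusted p is strictly below alpha = 0.05.

A Kruskal-Wallis p-value per feature is reported as the between-group
significance column but never used for retention.  Note a degeneracy:
with a single feature the normalised importance is identically 1 under
every labelling, so the permutation test is uninformative at d = 1.
Calibration (tested): on pure-noise tables the fraction of runs
retaining anything stays within the FDR budget; on tables with three
strong, one weak and two null features the strong ones are retained
and the null ones excluded in >= 90% of runs.

## Classification and evaluation

Retained features are z-scored with training-split statistics (8:2
stratified split), then classified by Random Forest (500 trees), KNN
(k = 5, Euclidean on z-scores) and RBF-SVM (C = 1, gamma = 1/d) — all
hyperparameters are config values since the sources give none.
Reports derive every metric from the 3x3 confusion matrix: accuracy,
per-class sensitivity TP/(TP+FN) and specificity TN/(TN+FP), and macro
F1 (arithmetic mean of per-class F1).  Zero-denominator conventions:
the affected metric is reported as 0 with a warning.  The fusion grid
evaluates each single feature, the cumulative fusions BC+MAI+VOB,
+VOH, +TI and all six, for each algorithm, on one shared split per
seed.  Whether the published grid came from one split or from
cross-validation is unknown; the package reports per-seed grids and
aggregates across seeds.

On the class-calibrated cohort (741 rows split 593/148, cv 0.15) the
four-feature fusion BC+MAI+VOB+VOH beats every single feature in
median RF accuracy over 20 seeds, and appending a pure-noise
trunk-inclination analogue does not improve it — the qualitative
structure the fusion experiment is meant to show.  The published
absolute accuracies come from farm data and are out of scope.

## Keypoint metrics

PCK@t counts a keypoint correct when its error is at most
t * max(H, W) of the heatmap extent.  AP/AR average precision and
recall over a strictness ladder; since the pose task pairs each
annotated point with exactly one prediction, FP = FN per threshold and
AP = AR unless a visibility mask removes points.  The exact ladder
behind published AP/AR values is unstated; the default scales the
conventional 0.50-0.95 (step 0.05) ladder by the 0.05 reference
threshold, and the ladder is configurable.  Object-keypoint-similarity
with per-keypoint sigmas was deliberately not used: no cow sigmas are
published, and the printed definitions are the normalised-distance
forms implemented here.

## Network forward mathematics

Implemented as pure-numpy forwards with property tests; no training.

- **ASSA**: scores S = QK^T/sqrt(d) + B per window; dense branch
  softmax(S)V; sparse branch ReLU(S)^2, row-normalised by its sum
  (rows with no positive score stay exactly zero), times V; output the
  convex fusion w1*DSA + w2*SSA with (w1, w2) a softmax of two
  learnable scalars — the simplest faithful reading of "weighted
  fusion".  Degenerate case: a single-token window with a non-positive
  score returns w1*V, because the sparse branch vanishes by
  construction.
- **FRFN**: partial 3x3 convolution on the leading quarter of the
  channels, linear expansion C -> 2C, GELU, split in half, depthwise
  3x3 convolution of one half gating the other elementwise
  (channelwise gating is the standard reading of the cited design's
  channel product), linear projection with GELU.
- **AGC**: Y = sum_k W_k X (A_k + B_k + C_k) + R(X) over Kv = 3
  spatial subsets; A_k is the symmetric degree normalisation
  D^-1/2 A D^-1/2 (epsilon degree on isolated nodes), B_k a learnable
  offset initialised to zero, C_k the row-softmax of embedded-Gaussian
  similarities.  The subset partition follows the root / centripetal /
  centrifugal convention around the lumbar node (the spine's centre);
  the sources do not define subsets for the cow skeleton, whose edges
  here are the spine chain poll-withers-lumbar-sacral plus scapulae
  attached at the withers and tuber coxae at the sacral tuber.

## Numerical choices

- Collinearity threshold for circumcircle fitting: triangle area
  below 1e-9 cm^2 gives curvature 0; coincident points raise.
- Sag inversion rejects curvatures whose radius is below half the
  chord (no circle exists).
- SSA row normalisation epsilon-free: zero-sum rows are returned as
  zeros rather than renormalised, preserving the "squared ReLU kills
  negative scores" property exactly.
- Standardisation rejects features whose training standard deviation
  is below 1e-12 relative to the mean scale.
- All randomness flows from one master seed through named
  `numpy.random.SeedSequence` substreams; forests receive 31-bit
  derived seeds.

## Problem sizes

The default test and acceptance runs use: 64-frame sequences at
160x96 px; screening calibration on 500-row tables with 25-tree
forests (the calibration properties are tree-count independent; small
forests keep the 51-refit permutation loop cheap); fusion grids on
741-row cohorts with 300-tree forests over 5-20 seeds.  These sizes
are the package's chosen desk-scale study conditions.

## Known limitations

- MAI depends on flow quality; the 30% round-trip tolerance reflects
  estimator bias near the half boundary, not extractor arithmetic.
- The synthetic cohort with cv = 0.15 separates classes more cleanly
  than farm data, so absolute fusion accuracies here are optimistic;
  only orderings are asserted.
- Keypoint detection itself (the trained network) is out of scope;
  the metrics and module forwards are implemented, the backbone and
  training are not.
- Hoof/limb features are invisible from overhead and not modelled.
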