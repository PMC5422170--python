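# Methods

This note documents the models, conventions and numerical choices of
the `paddyid` pipeline, and what the synthetic test bed does and does
not establish about behaviour on real seed images.

## Segmentation

The seed is assumed to be a single interior object on a contrasting
stage.  Two colour bands are thresholded independently and combined:

* **Red band**: the R channel, unchanged.
* **Hue band**: the HSV hue angle rescaled linearly from [0°, 360°) to
  8-bit integers [0, 255]; achromatic pixels (R = G = B), where hue is
  undefined, map to 0.  Keeping both bands 8-bit lets one Otsu code
  path serve both.
* **Smoothing**: one pass of a 3 × 3 box mean with edge replication,
  rounded to integer intensities (`smooth_size` config; 1 disables).
* **Otsu threshold**: exhaustive maximization of between-class variance
  over the 256-bin histogram; ties resolve to the smallest threshold; a
  constant image raises `DegenerateHistogramError`.
* **Polarity**: which side of the threshold is seed is per-band
  configurable; the `auto` default picks the class occupying the
  smaller share of the image border, since the seed is interior.
* **Combination**: pixelwise OR of the two band masks, hole filling
  (background regions not 4-connected to the border become foreground),
  then retention of the largest 8-connected component (the standard
  4/8 dual connectivity convention).  The mask is ANDed with the
  original image, blacking out the background.

With smoothing disabled, a noiseless two-tone rendering has a
two-valued histogram in each band, Otsu separates it exactly, and the
ground-truth silhouette is recovered with IoU = 1.0 (asserted in the
tests).  With the default 3 × 3 smoothing, boundary pixels take mixed
values and a pixel at a sharp corner can land on the wrong side of the
threshold, so exact recovery is not guaranteed even without noise; at
per-channel Gaussian noise σ = 5 the measured IoU stays above 0.998 on
the synthetic renderings (the acceptance bound is 0.98).

## Contour and key-point geometry

Coordinates are 0-based `(row, col)` with pixel centres on the integer
grid; lengths are Euclidean in pixels, angles in degrees.  The contour
is traced with Moore-neighbour tracing from the topmost-then-leftmost
foreground pixel, clockwise in image coordinates, stopping when the
first directed contour edge repeats (Jacob's criterion); 1-pixel-wide
spurs are traversed out and back.

* **Longest chord A̅B̅**: maximizes Euclidean distance over all contour
  point pairs.  The search runs over convex-hull vertices (which always
  contain the diameter endpoints) with exact integer squared distances;
  ties resolve to the lexicographically smallest ordered pair.  Tests
  assert equality with the all-pairs brute force.
* **Perpendicular chords**: the line through A + f·(B − A)
  perpendicular to A̅B̅ is intersected with the closed contour polygon
  (sign changes of the along-A̅B̅ offset, linear interpolation); the
  maximal-span pair of intersections is the chord.  f = 1/2 gives C̅D̅,
  f = 1/5 and 4/5 give the auxiliary P₁P₂ and P₃P₄ (measured but not
  part of the seven-feature vector).  The two half-lengths |C̅O̅| and
  |D̅O̅| are stored unlabeled: which half crosses the lemma versus the
  palea is not decidable from a silhouette.
* **Convex hull**: qhull, reordered clockwise-on-screen starting from
  the topmost-then-leftmost vertex; collinear edge-interior points are
  excluded; degenerate inputs return the extreme point(s).
* **Concavities**: for every pair of consecutive hull vertices the
  maximum perpendicular deficiency of the intervening contour arc from
  the hull bridge is computed; regions deeper than
  `min_concavity_depth` (default 1.0 px, suppressing rasterization
  jitter) are candidates and the two deepest are returned.  R_K is the
  deeper one (a pose-invariant labeling; the depth order, not the
  anatomical side, defines K).  Ties resolve to the earlier contour
  position.
* **Orientation**: the A̅B̅ endpoint nearer the midpoint of the two
  concavity apexes is relabeled A (the chaff-tip end).  Within each
  concavity the bridge endpoint nearer that tip end is the "u" point
  (K_u / L_u) and the farther one the "d" point — matching the
  along-contour order of the crucial points around the tip.
* **Tip metrics**: |L̅K̅| is the apex-to-apex distance.  h_c is the
  maximum perpendicular distance to the L̅K̅ line over the contour arc
  between the apexes that lies on the opposite side of that line from
  the silhouette centroid (shoelace centroid of the contour polygon).
* **Interior angle φ**: the angle between the direction vectors K→K_d
  and L→L_d, folded into [0°, 180°].  The published figures leave open
  whether φ is taken at the intersection of the extended segments or
  between direction vectors; the direction-vector convention is used
  because it is always defined, including for parallel segments.

## Features and normalization

The feature vector order is fixed: (|A̅B̅|, |C̅D̅|, |L̅K̅|, h_c, d_K, d_L,
φ).  Classifier inputs are normalized to [0, 1] by training-set min–max
ranges; at prediction time out-of-range values clip to [0, 1] and a
feature that was constant in training maps to 0.5.  The ranges are
serialized inside the model JSON so the column convention cannot drift.
Normalization bounds come from the training set only, the standard
practice when the published account does not say whether pooled data
were used.

## Classifiers

**BPNN.**  One hidden layer sized n_h = n_i + n_o + k, k ∈ {−2, 0, 2}
(8/10/12 nodes for this problem).  Logistic sigmoid on both layers —
consistent with inputs and one-hot targets in [0, 1]; a tanh option is
available in the config.  Training is online (per-sample) gradient
descent on squared error: no momentum, fixed learning rate (default
0.01), sample order reshuffled each epoch from the seeded generator,
weights and biases initialized uniformly in [−0.5, 0.5] from the same
seed.  The epoch mean squared error (over samples and output nodes) is
logged; training stops when it falls below the tolerance (default
0.01) or at `max_epochs` (default 10 000, a guard — the published
regime assumes convergence), in which case the model is returned
flagged `converged=False`.  Prediction is argmax over output
activations, ties to the earlier label.  Fixed seed and data give a
bitwise-identical weight trajectory.

**Gaussian Bayes.**  The comparison classifier is a full-covariance
Gaussian class-conditional model: per-class mean and covariance (the
published account does not pin down the exact Bayes variant; the
quadratic discriminant is the natural reading and is stated here as an
interpretation), priors proportional to class counts, and a ridge of
1e−6 · trace/d on each covariance diagonal for numerical definiteness.
Prediction maximizes the log posterior via Cholesky solves; tests check
it against independent multivariate-normal density evaluations.

**Evaluation.**  Confusion matrices store rows = predicted, columns =
true (the orientation under which the published column totals equal the
test-set sizes).  Per-class accuracy is the diagonal count over the
true-class column total and the average is trace over grand total, both
reported in percent rounded to 2 decimals.  `evaluate` accepts explicit
per-class totals for externally reported tables whose printed counts do
not sum to their printed totals — the published Bayes table has exactly
this defect, and its printed accuracies only reproduce from the printed
totals.

## Synthetic test bed

The generator produces silhouettes built from an ellipse body
(default semi-axes 150 × 55 px, the scale of a seed in a 640 × 480
close-up), a trapezoidal chaff tip protruding beyond the body apex
(default 25 px long, 30 px wide), and two flank concavities running
from the tip corners to "shoulder" vertices raised 2.5 px proud of the
ellipse just behind the exact tip tangency point (computed in closed
form).  Each concavity descends into a sharp V whose apex sits at the
specified perpendicular depth below the bridge chord; the construction
is verified at build time (simple polygon via shapely, bridge chords
are hull edges) and raises on violation.

This makes the ground truth exact by construction: d_K and d_L are the
specified depths, |L̅K̅| and φ follow from the constructed apex and
shoulder coordinates, h_c is the vertex maximum of a piecewise-linear
tip chain, and |A̅B̅| / |C̅D̅| are measured on the continuous polygon.
The pronounced corners (tip corners, shoulders, V apexes) keep every
key point localized to sub-pixel jitter after rasterization — a
deliberate design, since a key point on a locally flat arc can slide
many pixels under the pixel grid.

Rasterization bounds what recovery accuracy is achievable: a contour
pixel centre sits up to ~0.7 px from the continuous boundary, so
quantities that difference two key points (|L̅K̅|) can individually err
by up to ~1.5 px even though their mean absolute error is well under
0.5 px.  Accordingly the recovery tests assert the tight tolerances
(0.75 px on |L̅K̅|, h_c, d_K, d_L; 2° on φ) on the mean over ≥ 200
random poses, with per-sample caps (2.5 px / 6°) as regression guards;
|A̅B̅| and |C̅D̅| carry an additional systematic shortening of ~1–2 px
because rasterized extreme pixels lie inside the continuous outline.
Sub-pixel contour refinement would remove most of this error but is
out of scope: the pipeline is deliberately a pixel-grid method.

Three default variety populations draw the construction parameters
from independent normals whose means differ by ≥ 6 within-class
standard deviations in feature space (verified in the tests); the SDs
(1–1.5 px on body dimensions, 0.25 px on depths) model biological
spread at pixel scale.  Populations are sampled by drawing a spec,
rasterizing, and running the real geometry pipeline; draws whose
geometry fails are redrawn with a logged count, and a failure rate
above 50% raises.

**What passing these tests shows — and does not.**  The synthetic bed
proves the chain silhouette → features → classifier recovers known
geometry and separates populations that differ in that geometry.  It
does not emulate husk texture, specular highlights, soft shadows or
the true biological shape distributions, so the published accuracies on
real TK9/TN11/TK14 seeds (93–97% per class) are not reproduced here —
the original image set was never deposited.  What is reproduced from
the publication is its arithmetic: the accuracy computations from the
printed confusion matrices and the hidden-node sizing rule.

## Problem sizes and determinism

The acceptance-grade tests run 200 random silhouettes for geometry, 50
noisy renderings for segmentation, and 500 training + 150 held-out
samples per variety for the classifiers — sizes chosen to exercise the
published training regime while keeping the suite a few minutes long.
All randomness flows through explicitly seeded `numpy` generators;
feature CSVs and model JSONs are byte-identical across runs at a fixed
seed.
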