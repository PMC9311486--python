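# Methods

`padar` implements a two-branch retinal-image analysis system: a *screening*
branch that classifies color fundus photographs into five categories — healthy
control (HC), age-related macular degeneration (AMD), diabetic retinopathy
(DR), cellophane maculopathy (CM), pathological myopia (PM) — and renders
class-discriminative abnormality heatmaps; and a *monitoring* branch that
registers a patient's images over time and tracks candidate lesion sites
extracted from the heatmaps. Because clinical fundus archives are private,
everything is exercised on a built-in synthetic phantom generator with exact
ground truth; this note records the models, the tunable parameters, and the
design choices made where the design was genuinely open.

## Synthetic fundus phantoms

A phantom is a circular field of view (FOV, radius 0.47·S for image side S)
on a dark background containing: a warm orange fundus base with low-frequency
mottle, a bright slightly yellow optic disc (default center (0.72·S, 0.50·S),
radius 0.085·S), a darker macula (Gaussian darkening at (0.40·S, 0.50·S)),
and a recursively branching vessel tree of soft dark-red tubes seeded at the
disc. Vessels are not anatomically realistic; their purpose is keypoint-rich
texture so that feature-based registration has something to lock onto.

Lesion phenotypes are fixed per class: AMD carries 4–8 bright yellow drusen
spots near the macula; DR carries 3–5 dark red hemorrhage blobs plus 2–3
bright exudates; PM carries a bright peripapillary crescent on the
macula-facing side of the disc; CM carries a single broad, low-contrast sheen
over the macula with a fine shimmer texture; HC carries nothing. Default
radii are fractions of the image side (drusen 0.014–0.028·S, hemorrhage
0.02–0.04·S) so lesions remain resolvable at the 64-px desk input. Each
lesion is alpha-blended with a soft profile; the binary ground-truth mask is
the region where the profile exceeds 0.5. Additive Gaussian intensity noise
(default sd 0.02 in [0,1] units) is applied last. Every generator is a pure
function of its integer seeds.

Longitudinal series apply, per timepoint, a similarity motion about the image
center drawn from configurable ranges (defaults: rotation ±10°, translation
±5% of the side, scale 0.97–1.03), after scaling each lesion's radius by its
evolution multiplier (0 removes the lesion). The returned 2×3 matrices map
timepoint-1 coordinates to timepoint-t coordinates and are constructed, not
estimated, so registration accuracy can be scored exactly. Noise is redrawn
per timepoint. Cohorts arrange eyes as short series of repeat examinations
(small motions, fresh noise) under a patient/eye hierarchy; train/test
splitting and all cross-validation folds are grouped by eye.

What the phantoms do **not** emulate: camera optics, illumination gradients
and artifacts, media opacity, inter-patient anatomical variability, disease
severity continua, and co-morbid eyes. Passing the desk-scale recovery tests
therefore demonstrates that the pipeline machinery is correct and recovers
known structure under controlled conditions — not that the classifier would
reach any particular accuracy on clinical photographs.

## Screening model

The classifier is a VGG-style shared-weight convolutional feature extractor
with global average pooling, followed by seven binary heads and a fusion
layer. The heads are: one *main* head (retinopathy vs HC) and the six
pairwise heads over {AMD, DR, CM, PM}. Each head is three FC+ReLU layers
with dropout 0.2 and a 2-way softmax; head output index order follows the
head's (class_a, class_b) task tuple. The seven 2-way softmax outputs are
concatenated into a 14-dimensional *soft-target* vector — ordering: main,
then (AMD,DR), (AMD,CM), (AMD,PM), (DR,CM), (DR,PM), (CM,PM), serialized
with every checkpoint — consumed by a single FC softmax layer producing the
5-class prediction. At full scale (224-px input, block widths 64/128/256/512)
the last convolutional feature map is 14×14×512.

Training proceeds in three steps: (1) the backbone and main head are trained
jointly on retinopathy-vs-HC with 2-way cross-entropy; (2) the six pairwise
heads are trained on the *frozen* backbone's pooled features (a flag can
unfreeze; frozen is the default so all heads share one heatmap source);
(3) only the fusion layer is trained, with categorical cross-entropy on the
soft-target vectors. The optimizer is Adam with a reduce-on-plateau schedule
(full-scale defaults: initial rate 1e-5, floor 1e-8, divide by 10 after 10
stale epochs, batch 32). Before training, each class is augmented to a fixed
pool size (full-scale 5000/class) by horizontal flips, rotations uniform in
±36°, and width/height translations uniform in ±10% (black fill), then
bilinear-resized to the backbone input.

The layer stack (convolutions via im2col, max-pool, GAP, dense, inverted
dropout) is implemented directly on numpy with manual backprop; inference
runs with dropout disabled and is deterministic. Per-patient prediction is a
majority vote over the patient's image labels; ties are broken by the highest
mean class probability across the patient's images.

**Desk scale.** Tests and the acceptance run use a 4-block backbone
(widths 16/32/48/64) at 64-px input with 500 augmented images per class,
learning rate 2e-3, and ≤10 backbone epochs — about four minutes of CPU
training on the 5×10-eye cohort. Epoch budgets and the early-stopping
criterion are free parameters (patience on validation loss, grouped
validation eyes held out at 15%).

Nested cross-validation builds class-stratified, eye-grouped outer/inner
folds (5×5 by default); the inner folds are exposed for tuning and the
machinery accepts a pluggable trainer so the fold logic can be exercised
with a fast baseline.

## Grad-CAM++ heatmaps

For a target class score S (pre-softmax logit of the main head's
"retinopathy" output by default), with plain gradients g = ∂S/∂A of the last
convolutional activations A, per-location coefficients are computed with the
standard closed form for an exponentially transformed score,
α = g² / (2g² + (Σ_ab A) g³), channel weights w_k = Σ_ij α relu(g), and the
raw map is relu(Σ_k w_k A_k). The higher-order terms reduce to elementwise
powers of g, so only first-order backprop is required, and the gradient path
is verified against central finite differences in the tests. Plain gradients
are used rather than guided backpropagation (a toggle point in the API): the
guided variant zeroes negative upstream gradients and is not required for the
closed form. All-zero gradients legitimately yield an all-zero map.

Post-processing upsamples the raw map bilinearly to the display resolution
(512×512 by default) and min-max normalizes to [0,1]; a constant raw map
normalizes to all zeros, so a featureless response produces no candidates
downstream.

## Time-series registration

Image selection uses the optic-disc rule: the disc location must fall within
the central region (x_c ± 0.3·W, y_c ± 0.25·H); among qualifying
(macula-centered) images the reference minimizes the disc-to-center
distance, ties broken by earliest date then image id. The default disc
detector is matched filtering of a disc-sized circular kernel against the
green channel minus half the blue channel (suppressing pale non-disc
structures); it is a pluggable interface and accepts an injected detector or
the phantom ground truth.

Preprocessing: green channel → bilinear resample to 512×512 → FOV mask by
Otsu thresholding, hole filling (dark hemorrhages fall below the Otsu
threshold and must not punch holes in the solid FOV disc), and a 5-px disk
erosion at the rim → CLAHE (8×8 tiles, clip limit 0.02) → min-max
normalization, returned only inside the mask. Otsu runs on the resampled
green channel *before* CLAHE, and the rim erosion is interpreted as 5 px at
512×512; both are configurable.

Control points are scale/rotation-invariant keypoints with descriptors —
scikit-image SIFT by default, any detector with the same interface can be
injected — restricted to the FOV mask. Matching is nearest-neighbor in
descriptor space (Euclidean) with a Lowe ratio filter at 0.8 and an optional
symmetric cross-check. The affine transform mapping target coordinates onto
the reference frame is estimated by MSAC: minimal 3-point samples
(collinearity-rejected), truncated-quadratic scoring with a 3-px inlier
threshold, an adaptive iteration bound at 99% confidence (max 2000), least
squares refit on the final inliers, and a seeded RNG for bit-for-bit
reproducibility. Images and heatmaps are warped with the same transform
(bilinear, zero fill; nearest for masks).

## Lesion sites and temporal matching

On each processed heatmap H, candidate pixels satisfy H > E(H) + σ, where
E(H) and σ are the mean and *population* standard deviation over FOV pixels
(background zeros would bias the threshold downward; the comparison is
strictly greater so constant maps yield nothing). The number of clusters K
maximizes the mean silhouette coefficient over K = 2..10 of seeded k-means
labelings of the thresholded pixel coordinates; if the best silhouette falls
below s_min = 0.5 the pixels are treated as one site (splitting a single
compact blob plateaus near silhouette ≈ 0.4, while genuinely multi-site sets
score ≥ 0.8, so 0.5 cleanly separates the regimes). Above 1000 pixels the
silhouette is estimated on a seeded subsample. A K-component full-covariance
Gaussian mixture (k-means init, 5 restarts, tolerance 1e-4, seeded) then
assigns every thresholded pixel to its maximum-responsibility component, so
the site masks partition the thresholded mask exactly. Sites are sorted by
descending mean heatmap intensity. Clustering uses 2-D pixel coordinates
only; intensity enters through the threshold and the reported statistics.

Across registered timepoints, sites are matched to the reference sites by
shortest centroid distance with greedy one-to-one assignment in ascending
distance order, accepted within a 25-px gate at 512×512; unmatched
timepoints are recorded as absent. Greedy assignment (rather than optimal
bipartite matching) is simple and auditable; with the gate and well-separated
sites the two coincide.

For monitoring runs on phantoms the heatmap source is selectable: a trained
screening model (Grad-CAM++ per timepoint), an injected callable, or a
*synthetic* heatmap built from the ground-truth lesion masks (blurred union,
normalized) — the last decouples the tracking machinery from classifier
quality when scoring registration + clustering + matching against ground
truth.

## Metrics

Per-class precision, sensitivity, specificity, and F1 are one-vs-rest from
the multi-class confusion matrix; AUC is one-vs-rest on the score columns;
Cohen's kappa is the unweighted multi-class form. The macro average is the
unweighted arithmetic mean of per-class values (overall accuracy is reported
separately); classes absent from the truth yield missing rates and are
excluded from the macro with a warning.

## Numerical and reproducibility choices

- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` / `SeedSequence`); reruns of `simulate`,
  `register`, and `monitor` with a fixed config produce byte-identical JSON
  (floats rounded to 6 decimals, sorted keys, no timestamps; bundles embed a
  config hash, package version, and seeds).
- Degenerate rules are explicit: constant heatmaps → empty candidate mask;
  constant raw maps → all-zero processed map; fewer than 2 points → K = 1;
  equidistant descriptor neighbors are dropped by the ratio test; collinear
  MSAC samples are rejected; singular affines (|det| ≤ 1e-6) are errors.
- Problem sizes used by the test suite and the acceptance script: 64-px
  5-class cohorts (10 eyes/class, 4 images/eye) for training; 512-px phantom
  pairs/series for registration and tracking (20 pairs, 5 series); these
  sizes were chosen so the full suite runs on a single CPU in minutes while
  every contract is still exercised at the geometry the display pipeline
  uses (512×512).

## Known limitations

- Reported clinical-scale performance cannot be reproduced here: it requires
  a private hospital dataset and GPU-scale training; all quantitative claims
  in this package are recovery properties on synthetic data.
- The phantom lesion appearance model is a deliberate simplification; class
  separability at desk scale is by construction much higher than in clinical
  data.
- SURF itself is not available in this environment; the keypoint contract is
  "scale/rotation-invariant detector + descriptor", fulfilled by SIFT.
- The monitoring branch assumes affine inter-visit motion; deformable or
  projective changes, peripheral fields, and mosaicking are out of scope.
- No automated image-quality assessment: exclusions are manifest-level only.
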