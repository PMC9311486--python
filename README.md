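# padar

Retinopathy screening and longitudinal lesion monitoring for color fundus
photographs, exercisable end to end on built-in synthetic phantoms.

Clinicians screening for retinopathy — age-related macular degeneration
(AMD), diabetic retinopathy (DR), cellophane maculopathy (CM), pathological
myopia (PM) vs healthy controls (HC) — need two things from an automated
aid: a per-image/per-patient class call with an interpretable *where is the
abnormality* map, and a way to follow those abnormal regions across repeat
examinations. `padar` provides both branches:

- **Screening.** A shared-weight VGG-style feature extractor with global
  average pooling feeds seven binary classifiers — a main retinopathy-vs-HC
  head plus the C(4,2)=6 pairwise disease heads — whose 2-way softmax outputs
  form a 14-dimensional soft-target vector fused by a final FC layer into the
  5-class prediction. Training is three-step (backbone + main head, then the
  pairwise heads on frozen features, then the fusion layer alone), with
  flip/rotation/translation augmentation, Adam and a reduce-on-plateau
  schedule. Per-patient calls are majority votes over the patient's images.
  Abnormality heatmaps are Grad-CAM++ on the last convolutional layer:
  with g = ∂S/∂A the gradient of the class score S w.r.t. activations A,
  channel weights are w_k = Σ α·relu(g) with
  α = g² / (2g² + (Σ_ab A)·g³), and the map is relu(Σ_k w_k A_k),
  upsampled bilinearly to 512×512 and normalized to [0, 1].
- **Monitoring.** Macula-centered images are selected by the optic-disc rule
  (disc inside x_c ± 0.3·W, y_c ± 0.25·H; the reference minimizes the
  disc-to-center distance), preprocessed (green channel, CLAHE, Otsu FOV
  mask with rim erosion), registered to the reference via SIFT control
  points, ratio-test matching, and an MSAC-estimated affine transform, and
  the warped heatmaps are decomposed into candidate lesion sites: threshold
  at E(H) + σ, pick the cluster count K by maximum silhouette, fit a
  K-component Gaussian mixture, then match sites across timepoints by
  shortest centroid distance (gated, one-to-one).

Clinical fundus archives are private, so the package ships a synthetic
fundus generator (circular field of view, bright optic disc, darker macula,
branching vessels, class-specific lesion textures, seeded longitudinal
motions with exact ground-truth transforms and masks) that makes every stage
testable and reproducible. See `docs/methods.md` for models, parameters, and
design decisions.

## Worked example: tracking a shrinking lesion

```python
from padar import (PhantomSpec, SeriesSpec, generate_longitudinal_series,
                   RunConfig, run_monitoring)
from padar.phantom import LesionSpec

lesions = [LesionSpec("drusen", (180, 160), 14.0, 0.7),
           LesionSpec("drusen", (300, 300), 12.0, 0.7),
           LesionSpec("hemorrhage", (170, 330), 13.0, 0.7)]
spec = PhantomSpec(image_size=512, disease_class="AMD",
                   lesion_params=lesions, rng_seed=10)
series = SeriesSpec(n_timepoints=3, rotation_deg=10, translation_frac=0.05,
                    scale_range=(0.96, 1.04),
                    lesion_evolution=[[1, 1, 1], [0.7, 1, 1], [0.4, 1, 1]],
                    rng_seed=510)
images, transforms, truths = generate_longitudinal_series(spec, series)

result = run_monitoring(RunConfig(seed=0), series={"P000": images},
                        ground_truths={"P000": truths})
report = result["bundle"]["patients"]["P000"]
print("reference timepoint:", report["reference_index"] + 1)
for site in report["trajectories"]["sites"]:
    areas = [tp["area"] for tp in site["timepoints"]]
    dists = [tp["centroid_distance"] for tp in site["timepoints"]]
    print(f"site {site['site_id']} at {site['reference_centroid']}: "
          f"areas {areas}, match distances {dists} px")
```

Output:

```
reference timepoint: 3
site 0 at [156.79, 329.51]: areas [1051, 1100, 1095], match distances [0.173, 0.506, 0.0] px
site 1 at [283.43, 276.08]: areas [930, 979, 968], match distances [0.339, 0.252, 0.0] px
site 2 at [136.86, 155.15]: areas [1197, 731, 356], match distances [0.178, 0.569, 0.0] px
```

Three candidate sites are found and matched across all three visits with
sub-pixel centroid error after registration (the phantom moves by up to 10°
rotation, 5% translation, and 4% scale between visits). Sites 0 and 1 — the
stable hemorrhage and drusen — keep a near-constant area, while site 2 is the
drusen whose radius was programmed to shrink to 70% then 40%: its matched
area falls 1197 → 731 → 356 px². Here the heatmaps come from the phantom's
ground-truth masks, isolating the registration + clustering + tracking
machinery; pass a trained model instead (`run_monitoring(..., model=m)`) to
use Grad-CAM++ heatmaps.

Training and screening end to end (generates a 5×10-eye cohort at 64 px,
trains three steps, writes predictions, votes, heatmaps, and a metric table):

```sh
padar train --out runs/desk --seed 1
padar monitor --series runs/desk/manifest.csv --model runs/desk/model.padar.zip --out runs/monitor
```

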