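"""Synthetic fundus phantom generation with exact ground truth.

Generates circular-field-of-view retinal phantoms — bright optic disc, darker
macula, a branching vessel tree, and class-specific lesion textures — plus
longitudinal series related by known affine motions, and labeled cohorts with
a patient/eye hierarchy. Every generator is a pure function of its seeds, so
downstream classification, registration, and lesion-tracking stages can be
tested against exact ground truth (disc location, lesion masks, transforms)
without any external data.

Disease classes follow the screening taxonomy: HC (healthy control), AMD
(age-related macular degeneration; bright drusen spots), DR (diabetic
retinopathy; dark hemorrhage blobs plus bright exudates), PM (pathological
myopia; bright peripapillary crescent), and CM (cellophane maculopathy;
diffuse low-contrast sheen over the macula).

Coordinate convention throughout: (x, y) = (column, row), 0-based, pixel
centers at integer coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.transform import AffineTransform, warp

DISEASE_CLASSES = ("HC", "AMD", "DR", "CM", "PM")


@dataclass
class LesionSpec:
    """One lesion: a phenotype, a center (x, y) in pixels, a radius, a contrast."""

    kind: str  # "drusen" | "exudate" | "hemorrhage" | "crescent" | "sheen"
    center: tuple[float, float]
    radius: float
    contrast: float = 0.6


@dataclass
class PhantomSpec:
    """Parameters of one synthetic fundus phantom.

    Geometry defaults scale with ``image_size``; pass explicit values to
    override. ``lesion_params=None`` draws a class-typical lesion set from the
    seeded RNG; an explicit list pins the lesions exactly.
    """

    image_size: int = 512
    disc_center: tuple[float, float] | None = None
    disc_radius: float | None = None
    macula_center: tuple[float, float] | None = None
    fov_radius: float | None = None
    vessel_seed_count: int = 6
    disease_class: str = "HC"
    lesion_params: list[LesionSpec] | None = None
    noise_sd: float = 0.02
    rng_seed: int = 0

    def resolved(self) -> "PhantomSpec":
        """Fill size-dependent defaults and validate."""
        s = float(self.image_size)
        out = replace(
            self,
            disc_center=self.disc_center or (0.72 * s, 0.50 * s),
            disc_radius=self.disc_radius or 0.085 * s,
            macula_center=self.macula_center or (0.40 * s, 0.50 * s),
            fov_radius=self.fov_radius or 0.47 * s,
        )
        if out.disease_class not in DISEASE_CLASSES:
            raise ValueError(
                f"unknown disease class {out.disease_class!r}; "
                f"expected one of {DISEASE_CLASSES}"
            )
        if out.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        c = (s / 2.0, s / 2.0)
        for name, p in (("disc", out.disc_center), ("macula", out.macula_center)):
            if np.hypot(p[0] - c[0], p[1] - c[1]) >= out.fov_radius:
                raise ValueError(f"{name} center outside the field of view")
        if out.lesion_params is not None:
            for les in out.lesion_params:
                if les.radius <= 0:
                    raise ValueError("lesion radii must be > 0")
                d = np.hypot(les.center[0] - c[0], les.center[1] - c[1])
                if d + les.radius > out.fov_radius:
                    raise ValueError(
                        f"lesion at {les.center} (r={les.radius}) outside the FOV"
                    )
        return out


@dataclass
class SeriesSpec:
    """Longitudinal series: per-timepoint motion ranges and lesion evolution.

    ``motion_ranges`` holds maximal |rotation| in degrees, maximal |translation|
    as a fraction of the image side, and a (lo, hi) isotropic scale range; the
    actual motion of each timepoint >= 2 is drawn uniformly from these ranges.
    ``lesion_evolution[t][j]`` multiplies lesion j's radius at timepoint t
    (1-based t; multiplier 0 removes the lesion).
    """

    n_timepoints: int = 3
    rotation_deg: float = 10.0
    translation_frac: float = 0.05
    scale_range: tuple[float, float] = (0.97, 1.03)
    lesion_evolution: list[list[float]] | None = None
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_timepoints < 2:
            raise ValueError("a longitudinal series needs n_timepoints >= 2")
        lo, hi = self.scale_range
        if not (0.8 <= lo <= hi <= 1.25):
            raise ValueError("scale range must lie within [0.8, 1.25]")
        if self.lesion_evolution is not None:
            for row in self.lesion_evolution:
                if any(m < 0 for m in row):
                    raise ValueError("evolution multipliers must be >= 0")


@dataclass
class FundusImage:
    """An RGB fundus photograph plus acquisition metadata."""

    pixels: np.ndarray  # (H, W, 3) float32 in [0, 1]
    image_id: str = "img"
    patient_id: str = "P000"
    eye: str = "OD"
    date: str = "2020-01-01"
    field_name: str = "F2"

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class GroundTruth:
    """Exact phantom ground truth: disc location, lesion masks, label, FOV."""

    disc_location: tuple[float, float]
    lesion_masks: list[np.ndarray]
    class_label: str
    fov_mask: np.ndarray


# ---------------------------------------------------------------------------
# rendering primitives


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    return x, y


def _soft_disk(x, y, center, radius, softness=1.5) -> np.ndarray:
    r = np.hypot(x - center[0], y - center[1])
    return np.clip((radius - r) / softness + 0.5, 0.0, 1.0)


def _draw_vessels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Recursive random branching tree, rendered as soft dark tubes.

    Realism is not the goal; a texture-rich, seed-stable vessel map is (the
    registration stage needs repeatable keypoints).
    """
    s = spec.image_size
    canvas = np.zeros((s, s), dtype=np.float64)
    cx, cy = spec.disc_center
    fov_c = s / 2.0

    def stamp(x0, y0, x1, y1, width):
        n = max(2, int(np.hypot(x1 - x0, y1 - y0)))
        xs = np.linspace(x0, x1, n)
        ys = np.linspace(y0, y1, n)
        ix = np.clip(np.round(xs).astype(int), 0, s - 1)
        iy = np.clip(np.round(ys).astype(int), 0, s - 1)
        canvas[iy, ix] = np.maximum(canvas[iy, ix], width)

    def branch(x0, y0, angle, length, width, depth):
        if depth <= 0 or width < 0.35 or length < 2:
            return
        # slight random curvature, rendered as two sub-segments
        a1 = angle + rng.uniform(-0.25, 0.25)
        xm = x0 + 0.5 * length * np.cos(a1)
        ym = y0 + 0.5 * length * np.sin(a1)
        a2 = a1 + rng.uniform(-0.25, 0.25)
        x1 = xm + 0.5 * length * np.cos(a2)
        y1 = ym + 0.5 * length * np.sin(a2)
        stamp(x0, y0, xm, ym, width)
        stamp(xm, ym, x1, y1, width)
        if np.hypot(x1 - fov_c, y1 - fov_c) > spec.fov_radius * 1.05:
            return
        split = rng.uniform(0.35, 0.75)
        branch(x1, y1, a2 - split, length * rng.uniform(0.65, 0.85),
               width * 0.72, depth - 1)
        branch(x1, y1, a2 + split, length * rng.uniform(0.65, 0.85),
               width * 0.72, depth - 1)

    base_angle = np.arctan2(fov_c - cy, fov_c - cx)  # fan out across the fundus
    for i in range(spec.vessel_seed_count):
        a = base_angle + rng.uniform(-2.4, 2.4)
        branch(cx, cy, a, s * rng.uniform(0.16, 0.26), s / 190.0, depth=6)

    return np.clip(gaussian_filter(canvas, sigma=s / 450.0 + 0.6) * 2.2, 0.0, 1.0)


def _default_lesions(spec: PhantomSpec, rng: np.random.Generator) -> list[LesionSpec]:
    """Class-typical lesion sets, drawn from the phantom RNG."""
    s = spec.image_size
    mx, my = spec.macula_center
    cls = spec.disease_class
    out: list[LesionSpec] = []
    if cls == "HC":
        return out
    if cls == "AMD":
        for _ in range(rng.integers(4, 8)):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.02, 0.13) * s
            out.append(LesionSpec(
                "drusen",
                (mx + rad * np.cos(ang), my + rad * np.sin(ang)),
                rng.uniform(0.014, 0.028) * s,
                rng.uniform(0.55, 0.8),
            ))
    elif cls == "DR":
        for _ in range(rng.integers(3, 6)):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.05, 0.3) * s
            out.append(LesionSpec(
                "hemorrhage",
                (s / 2 + rad * np.cos(ang), s / 2 + rad * np.sin(ang)),
                rng.uniform(0.02, 0.04) * s,
                rng.uniform(0.6, 0.85),
            ))
        for _ in range(rng.integers(2, 4)):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.04, 0.18) * s
            out.append(LesionSpec(
                "exudate",
                (mx + rad * np.cos(ang), my + rad * np.sin(ang)),
                rng.uniform(0.012, 0.022) * s,
                rng.uniform(0.55, 0.8),
            ))
    elif cls == "PM":
        out.append(LesionSpec(
            "crescent", spec.disc_center, spec.disc_radius * 1.45,
            rng.uniform(0.6, 0.85),
        ))
    elif cls == "CM":
        out.append(LesionSpec(
            "sheen", (mx + rng.uniform(-0.02, 0.02) * s,
                      my + rng.uniform(-0.02, 0.02) * s),
            rng.uniform(0.13, 0.17) * s, rng.uniform(0.3, 0.45),
        ))
    return out


_LESION_COLORS = {
    "drusen": (1.00, 0.92, 0.55),
    "exudate": (1.00, 0.97, 0.75),
    "hemorrhage": (0.30, 0.03, 0.03),
    "crescent": (0.98, 0.93, 0.80),
    "sheen": (0.88, 0.83, 0.70),
}


def _render_lesion(les: LesionSpec, spec: PhantomSpec, x, y,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Return (weight map in [0,1], boolean mask) for one lesion."""
    if les.kind == "crescent":
        # peripapillary arc: annulus sector on the macula-facing side of the disc
        dx = x - les.center[0]
        dy = y - les.center[1]
        r = np.hypot(dx, dy)
        to_mac = np.arctan2(spec.macula_center[1] - les.center[1],
                            spec.macula_center[0] - les.center[0])
        ang = np.arctan2(dy, dx)
        dang = np.angle(np.exp(1j * (ang - to_mac)))
        inner = spec.disc_radius * 0.95
        w_rad = np.clip((les.radius - r) / 2.0 + 0.5, 0, 1) * \
            np.clip((r - inner) / 2.0 + 0.5, 0, 1)
        w_ang = np.clip((1.35 - np.abs(dang)) / 0.3 + 0.5, 0, 1)
        w = w_rad * w_ang
    elif les.kind == "sheen":
        r = np.hypot(x - les.center[0], y - les.center[1])
        w = np.exp(-0.5 * (r / (les.radius * 0.62)) ** 2)
        w *= 1.0 + 0.25 * np.sin(x / 2.1) * np.sin(y / 2.3)  # cellophane shimmer
        w = np.clip(w, 0, 1)
    else:
        w = _soft_disk(x, y, les.center, les.radius, softness=max(1.0, les.radius * 0.18))
    return w, w > 0.5


def generate_fundus(spec: PhantomSpec) -> tuple[FundusImage, GroundTruth]:
    """Render one phantom; deterministic for a fixed ``spec.rng_seed``.

    Returns the RGB image together with exact ground truth (FOV mask, disc
    location, per-lesion binary masks). HC phantoms carry no lesions.
    """
    spec = spec.resolved()
    rng = np.random.default_rng(spec.rng_seed)
    s = spec.image_size
    x, y = _grid(s)
    c = s / 2.0

    fov = _soft_disk(x, y, (c, c), spec.fov_radius, softness=2.0)
    fov_mask = fov > 0.5

    img = np.zeros((s, s, 3), dtype=np.float64)
    # fundus background: warm orange with a gentle radial falloff + mottle
    r_norm = np.hypot(x - c, y - c) / spec.fov_radius
    vignette = 1.0 - 0.25 * np.clip(r_norm, 0, 1) ** 2
    mottle = gaussian_filter(rng.normal(0.0, 1.0, (s, s)), sigma=s / 36.0)
    mottle = 0.05 * mottle / (np.abs(mottle).max() + 1e-12)
    base = np.stack([0.72 * vignette + mottle,
                     0.36 * vignette + 0.6 * mottle,
                     0.12 * vignette + 0.3 * mottle], axis=-1)
    img += base

    # macula: local darkening
    rm = np.hypot(x - spec.macula_center[0], y - spec.macula_center[1])
    mac = np.exp(-0.5 * (rm / (0.10 * s)) ** 2)
    img *= (1.0 - 0.38 * mac)[..., None]

    # optic disc: bright, slightly yellow
    disc_w = _soft_disk(x, y, spec.disc_center, spec.disc_radius,
                        softness=max(1.5, 0.012 * s))
    disc_col = np.array([0.97, 0.88, 0.60])
    img = img * (1 - disc_w[..., None]) + disc_col * disc_w[..., None]

    # vessels: dark red tubes (drawn after the disc so they emerge from it)
    vess = _draw_vessels(spec, rng)
    vcol = np.array([0.45, 0.08, 0.06])
    img = img * (1 - 0.85 * vess[..., None]) + vcol * 0.85 * vess[..., None]

    lesions = spec.lesion_params
    if lesions is None:
        lesions = _default_lesions(spec, rng)
        spec = replace(spec, lesion_params=lesions)
        spec.resolved()  # re-validate sampled geometry
    masks: list[np.ndarray] = []
    for les in lesions:
        w, mask = _render_lesion(les, spec, x, y, rng)
        col = np.array(_LESION_COLORS[les.kind])
        a = (w * les.contrast)[..., None]
        img = img * (1 - a) + col * a
        masks.append(mask & fov_mask)

    img *= fov[..., None]
    img += 0.02 * (1 - fov[..., None])  # faint camera background
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)

    fi = FundusImage(pixels=img, image_id=f"{spec.disease_class}_s{spec.rng_seed}")
    gt = GroundTruth(
        disc_location=tuple(spec.disc_center),
        lesion_masks=masks,
        class_label=spec.disease_class,
        fov_mask=fov_mask,
    )
    return fi, gt


# ---------------------------------------------------------------------------
# longitudinal series


def motion_matrix(rotation_deg: float, translation: tuple[float, float],
                  scale: float, center: tuple[float, float]) -> np.ndarray:
    """2x3 affine mapping reference (x, y) -> moved (x, y), about ``center``."""
    th = np.deg2rad(rotation_deg)
    R = scale * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    cx, cy = center
    t = np.array([cx, cy]) - R @ np.array([cx, cy]) + np.asarray(translation, float)
    return np.column_stack([R, t])


def apply_affine(matrix: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 2x3 matrix to points of shape (..., 2) in (x, y) order."""
    pts = np.asarray(points, dtype=np.float64)
    return pts @ matrix[:, :2].T + matrix[:, 2]


def warp_by_matrix(arr: np.ndarray, matrix: np.ndarray, order: int = 1) -> np.ndarray:
    """Resample ``arr`` so that output(x') = input(x) for x' = M x."""
    M = np.vstack([matrix, [0.0, 0.0, 1.0]])
    tf = AffineTransform(matrix=np.linalg.inv(M))
    out = warp(arr.astype(np.float64), tf, order=order, cval=0.0,
               preserve_range=True)
    if arr.dtype == bool:
        return out > 0.5
    return out.astype(arr.dtype)


def generate_longitudinal_series(
    spec: PhantomSpec, series: SeriesSpec
) -> tuple[list[FundusImage], list[np.ndarray], list[GroundTruth]]:
    """Render a seeded series of timepoints linked by known affine motions.

    Timepoint 1 is the phantom itself (identity motion). Each later timepoint
    renders the same anatomy with lesion radii scaled by the evolution
    multipliers, then warps everything by a motion drawn from the series
    ranges. Returned 2x3 matrices map timepoint-1 coordinates to timepoint-t
    coordinates exactly (they are constructed, not estimated).
    """
    spec = spec.resolved()
    series.validate()
    rng = np.random.default_rng(series.rng_seed)
    s = spec.image_size
    center = (s / 2.0, s / 2.0)

    if spec.lesion_params is None:
        base_rng = np.random.default_rng(spec.rng_seed)
        # consume the same stream positions as generate_fundus would
        lesions = _default_lesions(spec, base_rng)
        spec = replace(spec, lesion_params=lesions)
    n_lesions = len(spec.lesion_params)

    images, transforms, gts = [], [], []
    for t in range(series.n_timepoints):
        if t == 0:
            M = np.column_stack([np.eye(2), np.zeros(2)])
        else:
            rot = rng.uniform(-series.rotation_deg, series.rotation_deg)
            tr = rng.uniform(-series.translation_frac, series.translation_frac, 2) * s
            sc = rng.uniform(*series.scale_range)
            M = motion_matrix(rot, tuple(tr), sc, center)

        mult = [1.0] * n_lesions
        if series.lesion_evolution is not None and t < len(series.lesion_evolution):
            row = series.lesion_evolution[t]
            mult = [row[j] if j < len(row) else 1.0 for j in range(n_lesions)]

        evolved = [replace(l, radius=l.radius * m)
                   for l, m in zip(spec.lesion_params, mult) if m > 0]
        spec_t = replace(spec, lesion_params=evolved, noise_sd=0.0)
        frame, gt = generate_fundus(spec_t)

        disc_t = tuple(apply_affine(M, np.array(spec.disc_center)))
        if np.hypot(disc_t[0] - center[0], disc_t[1] - center[1]) >= spec.fov_radius:
            raise ValueError(
                f"timepoint {t + 1}: motion pushes the optic disc outside the FOV"
            )

        px = warp_by_matrix(frame.pixels, M, order=1)
        noise_rng = np.random.default_rng(
            np.random.SeedSequence([spec.rng_seed, series.rng_seed, t]).generate_state(1)[0]
        )
        if spec.noise_sd > 0:
            px = np.clip(px + noise_rng.normal(0, spec.noise_sd, px.shape), 0, 1)
        images.append(FundusImage(
            pixels=px.astype(np.float32),
            image_id=f"{spec.disease_class}_s{spec.rng_seed}_t{t + 1}",
            date=f"{2020 + t}-01-01",
        ))
        transforms.append(M)
        gts.append(GroundTruth(
            disc_location=disc_t,
            lesion_masks=[warp_by_matrix(m, M, order=0) for m in gt.lesion_masks],
            class_label=spec.disease_class,
            fov_mask=warp_by_matrix(gt.fov_mask, M, order=0),
        ))
    return images, transforms, gts


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class LabeledDataset:
    """A cohort of labeled phantom images with a patient/eye hierarchy."""

    images: list[FundusImage]
    ground_truths: list[GroundTruth]
    labels: list[str]
    eye_ids: list[str]
    patient_ids: list[str]
    seed: int = 0

    def __len__(self) -> int:
        return len(self.images)

    def pixel_array(self) -> np.ndarray:
        return np.stack([im.pixels for im in self.images])

    def grouped_split(self, test_frac: float = 0.2,
                      seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Grouped, class-stratified train/test split: no eye spans both sides."""
        rng = np.random.default_rng(self.seed if seed is None else seed)
        eyes = sorted(set(self.eye_ids))
        eye_label = {e: self.labels[self.eye_ids.index(e)] for e in eyes}
        test_eyes: set[str] = set()
        for cls in sorted(set(eye_label.values())):
            cls_eyes = [e for e in eyes if eye_label[e] == cls]
            n_test = max(1, int(round(test_frac * len(cls_eyes))))
            test_eyes.update(rng.permutation(cls_eyes)[:n_test].tolist())
        idx = np.arange(len(self.images))
        is_test = np.array([e in test_eyes for e in self.eye_ids])
        return idx[~is_test], idx[is_test]

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": self.patient_ids,
            "eye": [e.split("/")[-1] for e in self.eye_ids],
            "date": [im.date for im in self.images],
            "field": [im.field_name for im in self.images],
            "path": [f"{im.image_id}.png" for im in self.images],
            "label": self.labels,
        })


def generate_cohort(class_counts: dict[str, int], images_per_eye: int,
                    seed: int = 0, image_size: int = 512,
                    noise_sd: float = 0.02) -> LabeledDataset:
    """Generate a labeled cohort: ``class_counts`` eyes per class, each eye a
    short longitudinal series of ``images_per_eye`` repeat examinations with
    small motions. Reproducible for a fixed seed; eyes are independent."""
    if images_per_eye < 1 or not class_counts or all(v < 1 for v in class_counts.values()):
        raise ValueError("cohort needs at least one eye and one image per eye")
    ss = np.random.SeedSequence(seed)
    images, gts, labels, eye_ids, patient_ids = [], [], [], [], []
    eye_idx = 0
    for cls in sorted(class_counts):
        if cls not in DISEASE_CLASSES:
            raise ValueError(f"unknown class {cls!r}")
        for _ in range(class_counts[cls]):
            eye_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31 - 1))
            spec = PhantomSpec(image_size=image_size, disease_class=cls,
                               noise_sd=noise_sd, rng_seed=eye_seed)
            pid = f"P{eye_idx:03d}"
            eid = f"{pid}/OD"
            if images_per_eye == 1:
                im, gt = generate_fundus(spec)
                series = [(im, gt)]
            else:
                ims, _, tgts = generate_longitudinal_series(
                    spec,
                    SeriesSpec(n_timepoints=images_per_eye, rotation_deg=3.0,
                               translation_frac=0.02, scale_range=(0.98, 1.02),
                               rng_seed=eye_seed),
                )
                series = list(zip(ims, tgts))
            for t, (im, gt) in enumerate(series):
                im.patient_id = pid
                im.eye = "OD"
                im.image_id = f"{pid}_OD_t{t + 1}_{cls}"
                images.append(im)
                gts.append(gt)
                labels.append(cls)
                eye_ids.append(eid)
                patient_ids.append(pid)
            eye_idx += 1
    return LabeledDataset(images, gts, labels, eye_ids, patient_ids, seed=seed)


# ---------------------------------------------------------------------------
# disk I/O (PNG images, PNG masks, JSON ground truth, CSV manifest)


def save_image_png(image: FundusImage | np.ndarray, path: str | Path) -> None:
    px = image.pixels if isinstance(image, FundusImage) else image
    arr = np.clip(np.asarray(px, dtype=np.float64) * 255.0, 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(str(path))


def save_cohort(dataset: LabeledDataset, out_dir: str | Path,
                write_masks: bool = True) -> Path:
    """Write PNG images, ground-truth JSON + mask PNGs, and a manifest CSV."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    gt_records = []
    for im, gt in zip(dataset.images, dataset.ground_truths):
        save_image_png(im, out / "images" / f"{im.image_id}.png")
        rec = {
            "image_id": im.image_id,
            "disc_location": [round(float(v), 3) for v in gt.disc_location],
            "class_label": gt.class_label,
            "n_lesions": len(gt.lesion_masks),
        }
        if write_masks and gt.lesion_masks:
            mdir = out / "masks" / im.image_id
            mdir.mkdir(parents=True, exist_ok=True)
            for j, m in enumerate(gt.lesion_masks):
                Image.fromarray((m * 255).astype(np.uint8)).save(
                    str(mdir / f"lesion_{j}.png"))
        gt_records.append(rec)
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt_records, fh, indent=1, sort_keys=True)
    dataset.manifest().to_csv(out / "manifest.csv", index=False)
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks (1.0 when both are empty)."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
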