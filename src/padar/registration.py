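"""Time-series fundus image registration.

Pipeline: select macula-centered images via an optic-disc/ROI rule, choose
the reference image (disc closest to the ROI center), preprocess each image
(green channel, resample to 512x512, field-of-view mask by Otsu + edge
erosion, CLAHE, [0,1] normalization), extract scale/rotation-invariant
control points, match descriptors with a Lowe-style ratio test, estimate a
robust affine transform with MSAC (m-estimator sample consensus: truncated
quadratic scoring), and warp images and heatmaps into the reference frame.

The optic-disc detector is pluggable: the default finds the brightest compact
region after FOV masking and large-kernel smoothing; an injected detector or
ground-truth provider may replace it. The keypoint backend is scikit-image
SIFT by default; any object with a ``detect_and_extract(image)`` method
exposing ``keypoints`` (row, col), ``scales``, ``orientations``,
``descriptors`` can be injected.

Coordinates are (x, y) = (column, row), 0-based. Estimated 2x3 affine
matrices map target coordinates into the reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage.exposure import equalize_adapthist
from skimage.feature import SIFT
from skimage.filters import threshold_otsu
from skimage.morphology import disk, erosion
from skimage.transform import AffineTransform, resize, warp
from scipy.ndimage import binary_fill_holes
from sklearn.neighbors import NearestNeighbors

from .phantom import FundusImage


@dataclass
class DiscLocation:
    x: float
    y: float
    confidence: float = 1.0


@dataclass
class RoiRule:
    """Central region-of-interest rectangle: the disc of a macula-centered
    image falls within (x_c ± 0.3·W, y_c ± 0.25·H)."""

    half_width_frac: float = 0.30
    half_height_frac: float = 0.25

    def __post_init__(self):
        for f in (self.half_width_frac, self.half_height_frac):
            if not (0 < f <= 0.5):
                raise ValueError("ROI fractions must lie in (0, 0.5]")

    def contains(self, disc: DiscLocation, width: int, height: int) -> bool:
        cx, cy = width / 2.0, height / 2.0
        return (abs(disc.x - cx) <= self.half_width_frac * width and
                abs(disc.y - cy) <= self.half_height_frac * height)

    def distance_to_center(self, disc: DiscLocation, width: int,
                           height: int) -> float:
        return float(np.hypot(disc.x - width / 2.0, disc.y - height / 2.0))


@dataclass
class ControlPointSet:
    """Keypoints (x, y, scale, orientation) with fixed-length descriptors."""

    keypoints: np.ndarray  # (n, 4)
    descriptors: np.ndarray  # (n, d)
    image_id: str = ""

    def __len__(self) -> int:
        return len(self.keypoints)

    @property
    def xy(self) -> np.ndarray:
        return self.keypoints[:, :2]


@dataclass
class AffineResult:
    matrix: np.ndarray  # 2x3, target -> reference
    inlier_count: int
    inlier_rmse: float
    inlier_mask: np.ndarray | None = None


@dataclass
class RegistrationConfig:
    out_size: int = 512
    fov_erosion_px: int = 5  # "5 mm" is dimensionally inconsistent; 5 px at 512
    clahe_clip: float = 0.02
    clahe_tiles: int = 8
    otsu_before_clahe: bool = True
    ratio_threshold: float = 0.8
    cross_check: bool = False
    msac_threshold_px: float = 3.0
    msac_max_iters: int = 2000
    msac_confidence: float = 0.99
    rng_seed: int = 0


# ---------------------------------------------------------------------------
# optic disc


def detect_optic_disc(image: FundusImage | np.ndarray,
                      detector: Callable[[np.ndarray], DiscLocation] | None = None,
                      disc_radius_frac: float = 0.08) -> DiscLocation:
    """Locate the optic disc: the brightest compact disc-sized region.

    Default method: matched filtering of a disc-scale circular kernel against
    the green channel (minus half the blue channel, which suppresses pale
    non-disc structures), after checking that a field of view exists. Small
    bright lesions are averaged away by the disc-sized kernel. ``detector``
    injects an external method (e.g. a learned regressor or the phantom
    ground truth) as an exact passthrough."""
    px = image.pixels if isinstance(image, FundusImage) else image
    if detector is not None:
        return detector(px)
    gray = px.mean(axis=2) if px.ndim == 3 else px
    if gray.max() - gray.min() < 1e-6:
        raise ValueError("no field of view found (constant image)")
    fov = gray > threshold_otsu(gray) * 0.5
    if fov.sum() < 0.01 * fov.size:
        raise ValueError("no field of view found")
    s = gray.shape[0]
    score = (px[..., 1].astype(np.float64) - 0.5 * px[..., 2]
             if px.ndim == 3 else gray.astype(np.float64))
    r = disc_radius_frac * s
    n = int(2 * r) + 1
    yy, xx = np.mgrid[0:n, 0:n]
    kernel = ((xx - n // 2) ** 2 + (yy - n // 2) ** 2 <= r * r).astype(np.float64)
    kernel /= kernel.sum()
    from scipy.signal import fftconvolve
    sm = fftconvolve(score, kernel, mode="same")
    iy, ix = np.unravel_index(np.argmax(sm), sm.shape)
    peak = sm[iy, ix]
    conf = float(np.clip((peak - sm.mean()) / (np.abs(peak) + 1e-12), 0, 1))
    return DiscLocation(x=float(ix), y=float(iy), confidence=conf)


def select_reference(images: Sequence[FundusImage],
                     disc_locs: Sequence[DiscLocation],
                     rule: RoiRule | None = None
                     ) -> tuple[int, list[int]]:
    """Keep images whose disc lies inside the ROI rectangle (macula-centered
    views); the reference is the one with the smallest disc-to-ROI-center
    distance, ties broken by earliest date then lexicographic image id."""
    rule = rule or RoiRule()
    qualifying: list[int] = []
    dists: dict[int, float] = {}
    for i, (im, dl) in enumerate(zip(images, disc_locs)):
        h, w = im.pixels.shape[:2]
        dists[i] = rule.distance_to_center(dl, w, h)
        if rule.contains(dl, w, h):
            qualifying.append(i)
    if not qualifying:
        detail = ", ".join(f"{images[i].image_id}: {dists[i]:.1f}px"
                           for i in dists)
        raise ValueError(f"no macula-centered image qualifies (disc-to-ROI-center "
                         f"distances: {detail})")
    ref = min(qualifying,
              key=lambda i: (dists[i], images[i].date, images[i].image_id))
    return ref, qualifying


# ---------------------------------------------------------------------------
# preprocessing


def preprocess_for_registration(image: FundusImage | np.ndarray,
                                cfg: RegistrationConfig | None = None
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Green channel -> resample -> FOV mask (Otsu + erosion) -> CLAHE ->
    [0,1] normalization; the enhanced map is returned only inside the mask."""
    cfg = cfg or RegistrationConfig()
    px = image.pixels if isinstance(image, FundusImage) else image
    green = px[..., 1] if px.ndim == 3 else px
    if green.max() - green.min() < 1e-9:
        raise ValueError("degenerate constant image: Otsu threshold undefined")
    g = resize(green.astype(np.float64), (cfg.out_size, cfg.out_size), order=1,
               anti_aliasing=True, preserve_range=True)
    mask_src = g  # Otsu on the resampled green channel, before CLAHE
    fov = mask_src > threshold_otsu(mask_src)
    # the field of view is a solid disc; dark lesions (hemorrhages) fall
    # below the Otsu threshold and must not punch holes in it
    fov = binary_fill_holes(fov)
    if cfg.fov_erosion_px > 0:
        fov = erosion(fov, disk(cfg.fov_erosion_px))
    enh = equalize_adapthist(
        np.clip((g - g.min()) / (g.max() - g.min()), 0, 1),
        kernel_size=cfg.out_size // cfg.clahe_tiles, clip_limit=cfg.clahe_clip)
    lo, hi = enh.min(), enh.max()
    enh = (enh - lo) / (hi - lo) if hi > lo else np.zeros_like(enh)
    return enh * fov, fov


# ---------------------------------------------------------------------------
# control points


def extract_control_points(enhanced_map: np.ndarray, fov_mask: np.ndarray,
                           detector=None, image_id: str = "",
                           min_keypoints: int = 3) -> ControlPointSet:
    """Scale/rotation-invariant keypoints + descriptors inside the FOV mask."""
    det = detector if detector is not None else SIFT()
    try:
        det.detect_and_extract(enhanced_map)
    except RuntimeError as exc:  # skimage raises when no keypoints survive
        raise ValueError(f"insufficient texture for control points: {exc}")
    kp_rc = det.keypoints  # (row, col)
    xy = kp_rc[:, ::-1].astype(np.float64)
    inside = fov_mask[kp_rc[:, 0].astype(int), kp_rc[:, 1].astype(int)]
    scales = getattr(det, "scales", np.zeros(len(kp_rc)))
    orients = getattr(det, "orientations", np.zeros(len(kp_rc)))
    kps = np.column_stack([xy, np.asarray(scales, float),
                           np.asarray(orients, float)])[inside]
    desc = det.descriptors[inside].astype(np.float64)
    if len(kps) < min_keypoints:
        raise ValueError(
            f"insufficient texture: {len(kps)} control points inside the FOV "
            f"(need >= {min_keypoints})")
    return ControlPointSet(kps, desc, image_id=image_id)


def match_control_points(sx: ControlPointSet, sy: ControlPointSet,
                         ratio: float = 0.8,
                         cross_check: bool = False) -> np.ndarray:
    """Descriptor-space nearest-neighbor matches (Euclidean) with a Lowe-style
    ratio filter; pairs (i in SX, j in SY). Equidistant first and second
    neighbors (ratio 1) are dropped."""
    if len(sx) == 0 or len(sy) == 0:
        raise ValueError("control point sets must be non-empty")
    k = min(2, len(sy))
    nbrs = NearestNeighbors(n_neighbors=k).fit(sy.descriptors)
    dist, idx = nbrs.kneighbors(sx.descriptors)
    pairs = []
    for i in range(len(sx)):
        if k == 2 and dist[i, 0] >= ratio * dist[i, 1]:
            continue
        pairs.append((i, int(idx[i, 0])))
    if cross_check and pairs:
        back = NearestNeighbors(n_neighbors=1).fit(sx.descriptors)
        _, bidx = back.kneighbors(sy.descriptors)
        pairs = [(i, j) for i, j in pairs if int(bidx[j, 0]) == i]
    if not pairs:
        raise ValueError("no descriptor matches survive the ratio test")
    return np.asarray(pairs, dtype=int)


# ---------------------------------------------------------------------------
# robust affine estimation (MSAC)


def _fit_affine_lstsq(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Least-squares 2x3 affine mapping src -> dst ((x, y) points)."""
    n = len(src)
    A = np.hstack([src, np.ones((n, 1))])
    coef, *_ = np.linalg.lstsq(A, dst, rcond=None)
    return coef.T  # 2x3


def estimate_affine(matches: np.ndarray, sx: ControlPointSet,
                    sy: ControlPointSet,
                    threshold_px: float = 3.0, max_iters: int = 2000,
                    confidence: float = 0.99, seed: int = 0) -> AffineResult:
    """MSAC robust affine fit mapping SY (target) points onto SX (reference).

    Minimal 3-point samples; truncated-quadratic score (residual^2 capped at
    threshold^2); the best model is refit by least squares on its inliers.
    Deterministic for a fixed seed.
    """
    if len(matches) < 3:
        raise ValueError("need at least 3 matches for an affine fit")
    src = sy.xy[matches[:, 1]]  # target
    dst = sx.xy[matches[:, 0]]  # reference
    n = len(src)
    rng = np.random.default_rng(seed)
    t2 = threshold_px ** 2
    best_score = np.inf
    best_inliers: np.ndarray | None = None
    iters = max_iters
    it = 0
    while it < iters:
        it += 1
        pick = rng.choice(n, size=3, replace=False)
        tri = src[pick]
        area = abs((tri[1, 0] - tri[0, 0]) * (tri[2, 1] - tri[0, 1]) -
                   (tri[2, 0] - tri[0, 0]) * (tri[1, 1] - tri[0, 1]))
        if area < 1e-6:
            continue
        M = _fit_affine_lstsq(tri, dst[pick])
        res2 = ((src @ M[:, :2].T + M[:, 2] - dst) ** 2).sum(axis=1)
        score = np.minimum(res2, t2).sum()
        if score < best_score:
            best_score = score
            best_inliers = res2 < t2
            # adaptive iteration bound from the current inlier ratio
            w = max(best_inliers.mean(), 1e-3)
            needed = np.log(1 - confidence) / np.log(max(1 - w ** 3, 1e-12))
            iters = min(max_iters, max(int(np.ceil(needed)), 1))
    if best_inliers is None or best_inliers.sum() < 3:
        raise ValueError("consensus failed: fewer than 3 inliers")
    in_src, in_dst = src[best_inliers], dst[best_inliers]
    tri = in_src - in_src.mean(axis=0)
    if abs(np.linalg.det(tri.T @ tri)) < 1e-9:
        raise ValueError("degenerate (collinear) consensus set")
    M = _fit_affine_lstsq(in_src, in_dst)
    if abs(np.linalg.det(M[:, :2])) < 1e-6:
        raise ValueError("estimated affine is singular")
    res = in_src @ M[:, :2].T + M[:, 2] - in_dst
    rmse = float(np.sqrt((res ** 2).sum(axis=1).mean()))
    full_mask = np.zeros(n, dtype=bool)
    full_mask[np.flatnonzero(best_inliers)] = True
    return AffineResult(matrix=M, inlier_count=int(best_inliers.sum()),
                        inlier_rmse=rmse, inlier_mask=full_mask)


# ---------------------------------------------------------------------------
# warping & QC


def warp_to_reference(target: np.ndarray, transform: AffineResult | np.ndarray,
                      order: int = 1) -> np.ndarray:
    """Resample a target image or heatmap into the reference frame:
    out(x_ref) = target(M^{-1} x_ref), bilinear by default, zero fill."""
    M = transform.matrix if isinstance(transform, AffineResult) else transform
    if abs(np.linalg.det(M[:, :2])) < 1e-6:
        raise ValueError("singular transform")
    M3 = np.vstack([M, [0, 0, 1]])
    tf = AffineTransform(matrix=np.linalg.inv(M3))
    out = warp(target.astype(np.float64), tf, order=order, cval=0.0,
               preserve_range=True)
    if target.dtype == bool:
        return out > 0.5
    return out.astype(np.float64)


def mosaic_qc(reference: np.ndarray, warped: np.ndarray,
              tile: int = 64) -> np.ndarray:
    """Checkerboard composite of reference and warped target for visual QC."""
    if reference.shape != warped.shape:
        raise ValueError("reference and warped image shapes differ")
    h, w = reference.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    take_ref = ((yy // tile) + (xx // tile)) % 2 == 0
    if reference.ndim == 3:
        take_ref = take_ref[..., None]
    return np.where(take_ref, reference, warped)


def corner_reprojection_error(est: np.ndarray, truth: np.ndarray,
                              size: int = 512) -> float:
    """Max displacement of the image corners between two target->reference
    transforms (the standard registration accuracy summary)."""
    corners = np.array([[0, 0], [size - 1, 0], [0, size - 1],
                        [size - 1, size - 1]], dtype=np.float64)
    pe = corners @ est[:, :2].T + est[:, 2]
    pt = corners @ truth[:, :2].T + truth[:, 2]
    return float(np.max(np.hypot(*(pe - pt).T)))
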