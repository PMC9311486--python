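"""Candidate lesion-site extraction and longitudinal matching.

Adaptive clustering on a processed abnormality heatmap H in [0, 1]:

1. Threshold at E(H) + sigma — the mean plus the population standard
   deviation of the heatmap intensity (computed over FOV pixels when a mask
   is supplied), keeping strictly-greater pixels, so a constant heatmap
   yields no candidates.
2. Choose the number of clusters K in 2..k_max by maximum mean silhouette
   coefficient over the thresholded pixel coordinates; if the best silhouette
   is below ``s_min`` the pixels form a single site (K = 1).
3. Fit a K-component Gaussian mixture to the pixel coordinates; each pixel is
   assigned to its maximum-responsibility component, so the site masks
   partition the thresholded mask. Sites are sorted by descending mean
   heatmap intensity.
4. Across registered timepoints, match sites to the reference sites by
   shortest centroid distance: greedy one-to-one assignment in ascending
   distance order, accepted only within ``gate_px``; unmatched timepoints are
   recorded as absent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from sklearn.mixture import GaussianMixture

from .gradcam import Heatmap


@dataclass
class ThresholdRule:
    """Audit record of the applied threshold: E(H) + sigma, strictly greater."""

    mean: float
    sd: float

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    @property
    def threshold(self) -> float:
        return self.mean + self.sd


@dataclass
class LesionSite:
    site_id: int
    pixel_mask: np.ndarray
    centroid: tuple[float, float]  # intensity-weighted, (x, y)
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1) half-open
    mean_intensity: float
    mixture_weight: float = 1.0
    mixture_mean: tuple[float, float] | None = None
    mixture_cov: np.ndarray | None = None

    @property
    def area(self) -> int:
        return int(self.pixel_mask.sum())


@dataclass
class SiteTrajectory:
    reference_site_id: int
    matched_site_ids: list[int | None]  # per timepoint; None = absent
    centroid_distances: list[float | None]
    areas: list[int | None]
    mean_intensities: list[float | None]


def threshold_heatmap(H: Heatmap | np.ndarray,
                      fov_mask: np.ndarray | None = None
                      ) -> tuple[np.ndarray, ThresholdRule]:
    """Binary mask of pixels with H > E(H) + sigma.

    E(H) and sigma are the mean and *population* standard deviation over the
    FOV pixels (all pixels when no mask is given).
    """
    v = H.values if isinstance(H, Heatmap) else np.asarray(H, dtype=np.float64)
    if fov_mask is None:
        fov_mask = np.ones(v.shape, dtype=bool)
    if fov_mask.sum() == 0:
        raise ValueError("empty FOV: cannot compute heatmap statistics")
    vals = v[fov_mask]
    rule = ThresholdRule(mean=float(vals.mean()), sd=float(vals.std()))
    mask = (v > rule.threshold) & fov_mask
    return mask, rule


def mean_silhouette(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient (delegates to the standard estimator)."""
    return float(silhouette_score(points, labels))


def select_k(points: np.ndarray, k_max: int = 10, s_min: float = 0.5,
             seed: int = 0, silhouette_sample: int = 1000) -> int:
    """Number of clusters by maximum mean silhouette over K = 2..k_max.

    Fewer than 2 points, or a best silhouette below ``s_min`` (one compact
    blob), give K = 1. Clustering for the scan uses seeded k-means on the 2-D
    pixel coordinates. Above ``silhouette_sample`` points the silhouette is
    estimated on a seeded subsample (the exact O(n^2) computation is used for
    smaller sets).
    """
    pts = np.asarray(points, dtype=np.float64)
    n = len(pts)
    if n < 2 or len(np.unique(pts, axis=0)) < 2:
        return 1
    best_k, best_s = 1, -np.inf
    for k in range(2, min(k_max, n - 1) + 1):
        labels = KMeans(n_clusters=k, n_init=5, random_state=seed).fit_predict(pts)
        if len(np.unique(labels)) < 2:
            continue
        if n > silhouette_sample:
            s = float(silhouette_score(pts, labels,
                                       sample_size=silhouette_sample,
                                       random_state=seed))
        else:
            s = mean_silhouette(pts, labels)
        if s > best_s:
            best_k, best_s = k, s
    if best_s < s_min:
        return 1
    return best_k


def cluster_sites(mask: np.ndarray, H: Heatmap | np.ndarray, K: int,
                  seed: int = 0, n_init: int = 5,
                  tol: float = 1e-4) -> list[LesionSite]:
    """Gaussian-mixture clustering of the thresholded pixels into K candidate
    lesion sites (full covariance, k-means init, seeded). The site masks
    partition the input mask exactly. Sites are sorted by descending mean
    heatmap intensity and re-numbered 0..K-1."""
    v = H.values if isinstance(H, Heatmap) else np.asarray(H, dtype=np.float64)
    ys, xs = np.nonzero(mask)
    n = len(xs)
    if n == 0:
        raise ValueError("empty mask: no pixels to cluster")
    if K > n:
        raise ValueError(f"K={K} exceeds the {n} masked pixels")
    pts = np.column_stack([xs, ys]).astype(np.float64)
    if K == 1:
        labels = np.zeros(n, dtype=int)
        params = None
    else:
        gm = GaussianMixture(n_components=K, covariance_type="full",
                             n_init=n_init, tol=tol, random_state=seed,
                             init_params="kmeans",
                             reg_covar=1e-4).fit(pts)
        labels = gm.predict(pts)
        params = gm
    sites: list[LesionSite] = []
    for k in np.unique(labels):
        sel = labels == k
        m = np.zeros_like(mask)
        m[ys[sel], xs[sel]] = True
        w = v[ys[sel], xs[sel]]
        wsum = w.sum()
        if wsum <= 0:
            cx, cy = xs[sel].mean(), ys[sel].mean()
        else:
            cx = float((xs[sel] * w).sum() / wsum)
            cy = float((ys[sel] * w).sum() / wsum)
        sites.append(LesionSite(
            site_id=int(k), pixel_mask=m, centroid=(cx, cy),
            bbox=(int(xs[sel].min()), int(ys[sel].min()),
                  int(xs[sel].max()) + 1, int(ys[sel].max()) + 1),
            mean_intensity=float(w.mean()),
            mixture_weight=float(params.weights_[k]) if params is not None else 1.0,
            mixture_mean=tuple(params.means_[k]) if params is not None else (cx, cy),
            mixture_cov=params.covariances_[k] if params is not None else None,
        ))
    sites.sort(key=lambda s: -s.mean_intensity)
    for i, s in enumerate(sites):
        s.site_id = i
    return sites


def extract_sites(H: Heatmap | np.ndarray, fov_mask: np.ndarray | None = None,
                  k_max: int = 10, s_min: float = 0.5,
                  seed: int = 0) -> tuple[list[LesionSite], ThresholdRule]:
    """Full adaptive-clustering pipeline on one processed heatmap: threshold,
    silhouette-based K selection, GMM clustering. An empty thresholded mask
    yields no sites (healthy-looking heatmap)."""
    mask, rule = threshold_heatmap(H, fov_mask)
    if mask.sum() == 0:
        return [], rule
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(np.float64)
    K = select_k(pts, k_max=k_max, s_min=s_min, seed=seed)
    return cluster_sites(mask, H, K, seed=seed), rule


def match_sites_over_time(reference_sites: Sequence[LesionSite],
                          warped_timepoint_sites: Sequence[Sequence[LesionSite]],
                          gate_px: float = 25.0) -> list[SiteTrajectory]:
    """Match reference sites to each timepoint's sites by shortest centroid
    distance: greedy one-to-one in ascending distance, accepted iff the
    distance is within ``gate_px``. All sites must already live in the common
    reference frame."""
    trajs = [SiteTrajectory(r.site_id, [], [], [], [])
             for r in reference_sites]
    for sites_t in warped_timepoint_sites:
        pairs = []
        for ri, r in enumerate(reference_sites):
            for ti, t in enumerate(sites_t):
                d = float(np.hypot(r.centroid[0] - t.centroid[0],
                                   r.centroid[1] - t.centroid[1]))
                if d <= gate_px:
                    pairs.append((d, ri, ti))
        pairs.sort()
        used_r: set[int] = set()
        used_t: set[int] = set()
        assign: dict[int, tuple[int, float]] = {}
        for d, ri, ti in pairs:
            if ri in used_r or ti in used_t:
                continue
            used_r.add(ri)
            used_t.add(ti)
            assign[ri] = (ti, d)
        for ri, traj in enumerate(trajs):
            if ri in assign:
                ti, d = assign[ri]
                site = sites_t[ti]
                traj.matched_site_ids.append(site.site_id)
                traj.centroid_distances.append(d)
                traj.areas.append(site.area)
                traj.mean_intensities.append(site.mean_intensity)
            else:
                traj.matched_site_ids.append(None)
                traj.centroid_distances.append(None)
                traj.areas.append(None)
                traj.mean_intensities.append(None)
    return trajs


# stable site_id -> RGB color map used on every timepoint overlay
_SITE_COLORS = np.array([
    [0.90, 0.10, 0.10], [0.10, 0.70, 0.10], [0.15, 0.35, 0.95],
    [0.95, 0.75, 0.10], [0.75, 0.15, 0.85], [0.10, 0.80, 0.80],
    [0.95, 0.45, 0.10], [0.55, 0.55, 0.55],
])


def site_color(site_id: int) -> tuple[float, float, float]:
    return tuple(_SITE_COLORS[site_id % len(_SITE_COLORS)])


def _draw_box(img: np.ndarray, bbox: tuple[int, int, int, int],
              color: tuple[float, float, float], width: int = 2) -> None:
    x0, y0, x1, y1 = bbox
    h, w = img.shape[:2]
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    c = np.asarray(color)
    img[y0:y0 + width, x0:x1] = c
    img[max(y1 - width, 0):y1, x0:x1] = c
    img[y0:y1, x0:x0 + width] = c
    img[y0:y1, max(x1 - width, 0):x1] = c


def site_report(trajectories: Sequence[SiteTrajectory],
                reference_sites: Sequence[LesionSite],
                images: Sequence[np.ndarray],
                heatmaps: Sequence[Heatmap] | None = None,
                out_dir: str | Path | None = None,
                crop_half: int = 40) -> dict:
    """Trajectory report bundle: a JSON-serializable table plus (optionally
    written) per-timepoint overlays with color-coded site boxes — colors
    stable per site across timepoints — and per-site close-up crops."""
    table = []
    for traj in trajectories:
        ref = next(s for s in reference_sites
                   if s.site_id == traj.reference_site_id)
        table.append({
            "site_id": int(traj.reference_site_id),
            "color": [round(c, 3) for c in site_color(traj.reference_site_id)],
            "reference_centroid": [round(float(v), 2) for v in ref.centroid],
            "reference_area": ref.area,
            "timepoints": [
                {"matched_site": (int(m) if m is not None else None),
                 "centroid_distance": (round(float(d), 3)
                                       if d is not None else None),
                 "area": (int(a) if a is not None else None),
                 "mean_intensity": (round(float(mi), 4)
                                    if mi is not None else None)}
                for m, d, a, mi in zip(traj.matched_site_ids,
                                       traj.centroid_distances,
                                       traj.areas, traj.mean_intensities)],
        })
    report = {"schema_version": 1, "n_sites": len(trajectories),
              "n_timepoints": (len(trajectories[0].matched_site_ids)
                               if trajectories else 0),
              "sites": table}
    if out_dir is not None:
        from .phantom import save_image_png
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "trajectories.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        for t, img in enumerate(images):
            canvas = np.asarray(img, dtype=np.float64).copy()
            if canvas.ndim == 2:
                canvas = np.stack([canvas] * 3, axis=-1)
            for traj in trajectories:
                ref = next(s for s in reference_sites
                           if s.site_id == traj.reference_site_id)
                _draw_box(canvas, ref.bbox, site_color(ref.site_id))
            save_image_png(np.clip(canvas, 0, 1), out / f"overlay_t{t + 1}.png")
            for traj in trajectories:
                ref = next(s for s in reference_sites
                           if s.site_id == traj.reference_site_id)
                cx, cy = (int(round(v)) for v in ref.centroid)
                h, w = canvas.shape[:2]
                x0, x1 = max(cx - crop_half, 0), min(cx + crop_half, w)
                y0, y1 = max(cy - crop_half, 0), min(cy + crop_half, h)
                save_image_png(np.clip(canvas[y0:y1, x0:x1], 0, 1),
                               out / f"site{ref.site_id}_t{t + 1}_closeup.png")
    return report
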