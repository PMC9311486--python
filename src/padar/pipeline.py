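"""End-to-end orchestration: screening and longitudinal monitoring runs.

``run_screening`` generates (or accepts) a labeled cohort, trains the
three-step screening model on the grouped train split, predicts the held-out
eyes, votes per patient, renders Grad-CAM++ heatmaps, and computes the metric
table. ``run_monitoring`` runs the per-patient monitoring branch: optic-disc
detection, reference selection, preprocessing, control-point extraction and
matching, robust affine estimation, warping of images and heatmaps into the
reference frame, adaptive lesion-site clustering, and temporal site matching.

Every output bundle is self-describing (embedded config hash, package
version, seeds) and byte-identically reproducible for a fixed config: floats
are rounded before serialization and JSON keys are sorted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

from . import __version__
from .gradcam import Heatmap, gradcam_pp, postprocess_heatmap
from .lesions import extract_sites, match_sites_over_time, site_report
from .metrics import compute_metrics
from .phantom import (FundusImage, GroundTruth, LabeledDataset, generate_cohort,
                      save_cohort)
from .registration import (RegistrationConfig, detect_optic_disc,
                           estimate_affine, extract_control_points,
                           match_control_points, preprocess_for_registration,
                           select_reference, warp_to_reference)
from .screening import (BackboneConfig, ScreeningModel, TrainConfig,
                        predict_images, train_three_step, vote_patient)


@dataclass
class CohortConfig:
    class_counts: dict[str, int] = field(default_factory=lambda: {
        "HC": 10, "AMD": 10, "DR": 10, "CM": 10, "PM": 10})
    images_per_eye: int = 4
    image_size: int = 64
    noise_sd: float = 0.02


@dataclass
class ClusteringConfig:
    k_max: int = 10
    s_min: float = 0.5
    gate_px: float = 25.0


@dataclass
class RunConfig:
    """Single source of truth for a run: all seeds explicit, serialized into
    every output bundle."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    train: TrainConfig | None = None
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    test_frac: float = 0.2
    heatmap_size: int = 512

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            if callable(obj):
                return repr(obj)
            return obj
        return enc(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=repr)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _round_floats(obj, digits: int = 6):
    if isinstance(obj, float):
        return round(obj, digits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, digits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, digits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return round(float(obj), digits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_json(obj: dict, path: str | Path) -> None:
    """Deterministic JSON writer: rounded floats, sorted keys, no timestamps."""
    with open(path, "w") as fh:
        json.dump(_round_floats(obj), fh, indent=1, sort_keys=True)
        fh.write("\n")


def provenance(cfg: RunConfig) -> dict:
    return {"package": "padar", "version": __version__,
            "config": cfg.to_dict(), "config_hash": cfg.config_hash(),
            "seed": cfg.seed}


# ---------------------------------------------------------------------------
# screening branch


def run_screening(cfg: RunConfig, dataset: LabeledDataset | None = None,
                  model: ScreeningModel | None = None,
                  out_dir: str | Path | None = None) -> dict:
    """Screening end-to-end: cohort -> three-step training -> held-out
    predictions, per-patient votes, heatmaps, metric table."""
    dataset = dataset or generate_cohort(
        cfg.cohort.class_counts, cfg.cohort.images_per_eye, seed=cfg.seed,
        image_size=cfg.cohort.image_size, noise_sd=cfg.cohort.noise_sd)
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    train_idx, test_idx = dataset.grouped_split(cfg.test_frac, seed=cfg.seed)
    tcfg = cfg.train or TrainConfig.desk(seed=cfg.seed)
    if model is None:
        model, log = train_three_step(dataset, tcfg, backbone_cfg=cfg.backbone,
                                      train_idx=train_idx)
    else:
        log = None

    size = model.backbone_cfg.input_size
    X = np.stack([
        im.pixels if im.pixels.shape[0] == size else
        resize(im.pixels, (size, size), order=1,
               preserve_range=True).astype(np.float32)
        for im in dataset.images])
    pred = predict_images(model, X)

    per_image = []
    heatmaps: list[Heatmap] = []
    for i, im in enumerate(dataset.images):
        raw = gradcam_pp(model, X[i], image_id=im.image_id)
        heatmaps.append(postprocess_heatmap(raw, out_size=cfg.heatmap_size))
        per_image.append({
            "image_id": im.image_id, "patient_id": im.patient_id,
            "label": dataset.labels[i], "predicted": pred["labels"][i],
            "split": "test" if i in set(test_idx.tolist()) else "train",
            "class_probs": [float(p) for p in pred["class_probs"][i]],
            "soft_targets": [float(p) for p in pred["soft_targets"][i]],
            "heatmap_mean": heatmaps[-1].mean, "heatmap_sd": heatmaps[-1].sd,
        })

    votes = {}
    for pid in sorted(set(dataset.patient_ids)):
        idx = [i for i, p in enumerate(dataset.patient_ids) if p == pid]
        pp = vote_patient([pred["labels"][i] for i in idx],
                          pred["class_probs"][idx], patient_id=pid)
        votes[pid] = {"voted_label": pp.voted_label,
                      "vote_counts": pp.vote_counts,
                      "true_label": dataset.labels[idx[0]]}

    y_true = [dataset.labels[i] for i in test_idx]
    table = compute_metrics(y_true, [pred["labels"][i] for i in test_idx],
                            pred["class_probs"][test_idx])
    bundle = {"provenance": provenance(cfg),
              "n_images": len(dataset),
              "train_idx": train_idx.tolist(), "test_idx": test_idx.tolist(),
              "per_image": per_image, "patient_votes": votes,
              "metrics": table.to_dict()}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_json(bundle, out / "screening_report.json")
        if log is not None:
            log.to_csv(out / "training_log.csv")
        model.save(out / "model.padar.zip")
        from .gradcam import save_heatmap
        hdir = out / "heatmaps"
        hdir.mkdir(exist_ok=True)
        for h in heatmaps:
            save_heatmap(h, hdir / f"{h.source_image_id}.png")
    return {"bundle": bundle, "model": model, "dataset": dataset,
            "heatmaps": heatmaps, "metrics": table,
            "train_idx": train_idx, "test_idx": test_idx,
            "predictions": pred}


# ---------------------------------------------------------------------------
# monitoring branch


def synthetic_heatmap_from_masks(lesion_masks: Sequence[np.ndarray],
                                 shape: tuple[int, int],
                                 sigma: float = 4.0) -> Heatmap:
    """Synthetic abnormality heatmap built directly from ground-truth lesion
    masks (blurred union, min-max normalized). A stand-in heatmap source for
    exercising the monitoring machinery on phantoms with known truth,
    independently of any trained screening model."""
    acc = np.zeros(shape, dtype=np.float64)
    for m in lesion_masks:
        mm = m.astype(np.float64)
        if mm.shape != shape:
            mm = resize(mm, shape, order=1, preserve_range=True)
        acc = np.maximum(acc, mm)
    acc = gaussian_filter(acc, sigma=sigma)
    if acc.max() > 0:
        acc = acc / acc.max()
    return Heatmap(values=acc, processed=True, target_class="retinopathy")


def register_series(images: Sequence[FundusImage],
                    cfg: RegistrationConfig | None = None,
                    disc_detector: Callable | None = None) -> dict:
    """Registration branch for one eye's time series.

    Returns the reference index, per-timepoint estimated 2x3 matrices
    (target -> reference; identity for the reference itself), warped images,
    preprocessing masks, and per-timepoint QC numbers. Timepoints whose
    registration fails are flagged ``unregistered`` and carry no transform.
    """
    cfg = cfg or RegistrationConfig()
    discs = [detect_optic_disc(im, detector=disc_detector) for im in images]
    ref_idx, qualifying = select_reference(images, discs)
    prep = [preprocess_for_registration(im, cfg) for im in images]
    ref_map, ref_mask = prep[ref_idx]
    sx = extract_control_points(ref_map, ref_mask,
                                image_id=images[ref_idx].image_id)
    results: list[dict] = []
    transforms: list[np.ndarray | None] = []
    warped: list[np.ndarray | None] = []
    for t, im in enumerate(images):
        rec = {"image_id": im.image_id, "qualifies": t in qualifying}
        img512 = resize(im.pixels, (cfg.out_size, cfg.out_size), order=1,
                        preserve_range=True)
        if t == ref_idx:
            M = np.column_stack([np.eye(2), np.zeros(2)])
            rec.update(status="reference", inliers=len(sx), rmse=0.0,
                       keypoints=len(sx))
            transforms.append(M)
            warped.append(img512)
        else:
            try:
                sy = extract_control_points(prep[t][0], prep[t][1],
                                            image_id=im.image_id)
                matches = match_control_points(sx, sy, ratio=cfg.ratio_threshold,
                                               cross_check=cfg.cross_check)
                est = estimate_affine(matches, sx, sy,
                                      threshold_px=cfg.msac_threshold_px,
                                      max_iters=cfg.msac_max_iters,
                                      confidence=cfg.msac_confidence,
                                      seed=cfg.rng_seed)
                transforms.append(est.matrix)
                warped.append(warp_to_reference(img512, est))
                rec.update(status="registered", keypoints=len(sy),
                           n_matches=len(matches), inliers=est.inlier_count,
                           rmse=round(est.inlier_rmse, 4),
                           matrix=[[round(v, 6) for v in row]
                                   for row in est.matrix])
            except ValueError as exc:
                transforms.append(None)
                warped.append(None)
                rec.update(status="unregistered", reason=str(exc))
        results.append(rec)
    return {"reference_index": ref_idx, "transforms": transforms,
            "warped_images": warped, "report": results,
            "fov_mask": ref_mask, "preprocessed": prep,
            "disc_locations": [(d.x, d.y) for d in discs]}


def run_monitoring(cfg: RunConfig,
                   series: dict[str, list[FundusImage]] | None = None,
                   heatmap_fn: Callable[[FundusImage], Heatmap] | None = None,
                   ground_truths: dict[str, list[GroundTruth]] | None = None,
                   model: ScreeningModel | None = None,
                   out_dir: str | Path | None = None) -> dict:
    """Monitoring end-to-end for one or more patients' time series.

    The heatmap source is, in order of precedence: an injected ``heatmap_fn``;
    the trained ``model`` (Grad-CAM++ on each timepoint); or, when phantom
    ``ground_truths`` are supplied, a synthetic heatmap built from the true
    lesion masks. Patients with fewer than 2 timepoints are skipped with a
    logged reason.
    """
    if series is None:
        raise ValueError("run_monitoring requires per-patient image series")
    rcfg = cfg.registration
    ccfg = cfg.clustering
    out: dict = {"provenance": provenance(cfg), "patients": {}}
    artifacts: dict = {}
    for pid in sorted(series):
        images = series[pid]
        if len(images) < 2:
            out["patients"][pid] = {"status": "skipped",
                                    "reason": "fewer than 2 timepoints"}
            continue
        reg = register_series(images, rcfg)
        size = rcfg.out_size

        def make_heatmap(t: int) -> Heatmap:
            if heatmap_fn is not None:
                return heatmap_fn(images[t])
            if model is not None:
                s = model.backbone_cfg.input_size
                x = resize(images[t].pixels, (s, s), order=1,
                           preserve_range=True).astype(np.float32)
                return postprocess_heatmap(gradcam_pp(model, x), out_size=size)
            if ground_truths is not None:
                gt = ground_truths[pid][t]
                sigma = 4.0 * size / 512.0
                return synthetic_heatmap_from_masks(
                    gt.lesion_masks, (size, size), sigma=sigma)
            raise ValueError("no heatmap source: pass heatmap_fn, model, "
                             "or ground_truths")

        ref_idx = reg["reference_index"]
        fov = reg["fov_mask"]
        per_tp_sites = []
        registered_t: list[int] = []
        for t in range(len(images)):
            if reg["transforms"][t] is None:
                continue
            h = make_heatmap(t)
            hw = warp_to_reference(h.values, reg["transforms"][t]) \
                if t != ref_idx else h.values
            sites, rule = extract_sites(
                Heatmap(values=np.clip(hw, 0, 1), processed=True),
                fov_mask=fov, k_max=ccfg.k_max, s_min=ccfg.s_min, seed=cfg.seed)
            per_tp_sites.append(sites)
            registered_t.append(t)
        ref_pos = registered_t.index(ref_idx)
        ref_sites = per_tp_sites[ref_pos]
        trajs = match_sites_over_time(ref_sites, per_tp_sites,
                                      gate_px=ccfg.gate_px)
        pdir = None if out_dir is None else Path(out_dir) / pid
        rep = site_report(trajs, ref_sites,
                          [w for w in reg["warped_images"] if w is not None],
                          out_dir=pdir)
        out["patients"][pid] = {
            "status": "ok", "reference_index": ref_idx,
            "registered_timepoints": registered_t,
            "registration": reg["report"], "trajectories": rep,
        }
        artifacts[pid] = {"registration": reg, "sites": per_tp_sites,
                          "trajectories": trajs}
    if out_dir is not None:
        outp = Path(out_dir)
        outp.mkdir(parents=True, exist_ok=True)
        write_json(out, outp / "monitoring_report.json")
    return {"bundle": out, "artifacts": artifacts}


def evaluate_tracking(trajectories, reference_sites, gt_masks_ref: Sequence[np.ndarray],
                      persisting: Sequence[int] | None = None,
                      max_centroid_px: float = 10.0) -> dict:
    """Score temporal tracking against phantom ground truth.

    A ground-truth lesion (mask in the reference frame) counts as *tracked*
    when the reference site overlapping it most is matched at every timepoint
    and each matched centroid distance stays below ``max_centroid_px``.
    ``persisting`` restricts scoring to the given lesion indices (lesions that
    never disappear)."""
    idxs = list(range(len(gt_masks_ref))) if persisting is None else list(persisting)
    per_lesion = []
    for j in idxs:
        gm = np.asarray(gt_masks_ref[j], bool)
        overlaps = [np.logical_and(gm, s.pixel_mask).sum()
                    for s in reference_sites]
        if not overlaps or max(overlaps) == 0:
            per_lesion.append({"lesion": j, "tracked": False,
                               "reason": "no overlapping site"})
            continue
        site = reference_sites[int(np.argmax(overlaps))]
        traj = next(t for t in trajectories
                    if t.reference_site_id == site.site_id)
        ok = (all(m is not None for m in traj.matched_site_ids) and
              all(d is not None and d < max_centroid_px
                  for d in traj.centroid_distances))
        per_lesion.append({"lesion": j, "tracked": bool(ok),
                           "site": site.site_id,
                           "distances": [None if d is None else round(float(d), 3)
                                         for d in traj.centroid_distances]})
    frac = (np.mean([r["tracked"] for r in per_lesion])
            if per_lesion else float("nan"))
    return {"tracked_fraction": float(frac), "per_lesion": per_lesion}


def simulate(cfg: RunConfig, out_dir: str | Path | None = None
             ) -> LabeledDataset:
    """Generate (and optionally write) the configured cohort, with a
    deterministic JSON summary."""
    ds = generate_cohort(cfg.cohort.class_counts, cfg.cohort.images_per_eye,
                         seed=cfg.seed, image_size=cfg.cohort.image_size,
                         noise_sd=cfg.cohort.noise_sd)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_cohort(ds, out)
        summary = {"provenance": provenance(cfg), "n_images": len(ds),
                   "n_eyes": len(set(ds.eye_ids)),
                   "labels": {c: ds.labels.count(c)
                              for c in sorted(set(ds.labels))},
                   "checksum": hashlib.sha256(
                       ds.pixel_array().tobytes()).hexdigest()}
        write_json(summary, out / "cohort_summary.json")
    return ds
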