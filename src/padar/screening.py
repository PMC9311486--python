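"""Multi-binary-classifier retinopathy screening model.

Architecture: a shared-weight VGG-style convolutional feature extractor with
global average pooling feeds seven binary classifier heads — one *main* head
separating retinopathy from healthy controls (HC), and the six pairwise heads
over the four disease classes {AMD, DR, CM, PM} — whose 2-way softmax outputs
are concatenated into a 14-dimensional soft-target vector consumed by a final
fully connected fusion layer that predicts the 5-way class. Each head is
three FC+ReLU+dropout(0.2) layers followed by a 2-way softmax.

Training follows a three-step protocol: (1) backbone + main head on the
retinopathy-vs-HC task; (2) the six pairwise heads on the frozen backbone's
pooled features; (3) the fusion layer alone on the soft-target vectors.
All steps use Adam with a reduce-on-plateau learning-rate schedule and
(binary/categorical) cross-entropy. Per-patient predictions are obtained by
majority voting over the patient's images, ties broken by highest mean class
probability.

The full-scale configuration (224x224 input, 14x14x512 feature map) is
provided; the desk configuration (64x64 input, 4 blocks) trains on CPU in
minutes and is the default for tests and examples.
"""

from __future__ import annotations

import hashlib
import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from skimage.transform import AffineTransform, resize, warp

from . import nn
from .phantom import FundusImage, LabeledDataset

CLASSES = ("HC", "AMD", "DR", "CM", "PM")
DISEASES = ("AMD", "DR", "CM", "PM")
#: Fixed head ordering: main first, then pairwise lexicographic in DISEASES
#: order. Serialized with every checkpoint.
HEAD_TASKS: tuple[tuple[str, str], ...] = (
    ("retinopathy", "HC"),
    ("AMD", "DR"), ("AMD", "CM"), ("AMD", "PM"),
    ("DR", "CM"), ("DR", "PM"), ("CM", "PM"),
)


@dataclass
class BackboneConfig:
    """VGG-style stack: per-block convolution widths, each block ending in a
    2x2 max-pool. The feature map is the output of the last block."""

    input_size: int = 64
    block_widths: tuple[int, ...] = (16, 32, 48, 64)
    convs_per_block: tuple[int, ...] | None = None
    pretrained_init: Callable[["ScreeningModel"], None] | None = None

    @property
    def feature_map_shape(self) -> tuple[int, int, int]:
        side = self.input_size // (2 ** len(self.block_widths))
        return (side, side, self.block_widths[-1])

    @staticmethod
    def full_scale() -> "BackboneConfig":
        """224 input, four blocks ending at 512 channels -> (14, 14, 512)."""
        return BackboneConfig(input_size=224, block_widths=(64, 128, 256, 512),
                              convs_per_block=(2, 2, 3, 3))


@dataclass
class BinaryHeadConfig:
    task: tuple[str, str]
    fc_widths: tuple[int, int, int] = (32, 16, 8)
    dropout_rate: float = 0.2


@dataclass
class TrainConfig:
    """Optimization hyperparameters (full-scale defaults; see desk())."""

    lr_init: float = 1e-5
    lr_floor: float = 1e-8
    lr_decay_factor: float = 10.0
    patience_epochs: int = 10
    batch_size: int = 32
    per_class_augmented_count: int = 5000
    max_epochs_backbone: int = 60
    max_epochs_heads: int = 60
    max_epochs_fusion: int = 120
    early_stop_patience: int = 12
    val_frac: float = 0.15
    rng_seed: int = 0

    def __post_init__(self):
        if self.lr_floor >= self.lr_init:
            raise ValueError("lr_floor must be below lr_init")
        if self.patience_epochs < 1:
            raise ValueError("patience must be >= 1")

    @staticmethod
    def desk(seed: int = 0) -> "TrainConfig":
        """Desk-scale settings: small augmented pools and a learning rate
        sized for the small backbone so CPU training finishes in minutes."""
        return TrainConfig(lr_init=2e-3, lr_floor=1e-6, patience_epochs=4,
                           per_class_augmented_count=500,
                           max_epochs_backbone=10, max_epochs_heads=40,
                           max_epochs_fusion=80, early_stop_patience=4,
                           rng_seed=seed)


@dataclass
class PatientPrediction:
    patient_id: str
    image_labels: list[str]
    voted_label: str
    vote_counts: dict[str, int]


@dataclass
class TrainingLog:
    """Per-epoch records for each training step: loss, val loss, lr."""

    records: list[dict] = field(default_factory=list)

    def add(self, step: str, epoch: int, train_loss: float,
            val_loss: float, lr: float) -> None:
        self.records.append({"step": step, "epoch": epoch,
                             "train_loss": float(train_loss),
                             "val_loss": float(val_loss), "lr": float(lr)})

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame(self.records).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# augmentation


def apply_augmentation(pixels: np.ndarray, flip: bool, rotation_deg: float,
                       translate_frac: tuple[float, float],
                       out_size: int) -> np.ndarray:
    """Deterministic augmentation: optional horizontal flip, rotation about
    the image center, fractional translation (black fill), then bilinear
    resize to ``out_size``."""
    img = pixels[:, ::-1] if flip else pixels
    h, w = img.shape[:2]
    if h > 1 and w > 1 and (rotation_deg != 0 or any(translate_frac)):
        th = np.deg2rad(rotation_deg)
        c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        t = c - R @ c + np.array([translate_frac[0] * w, translate_frac[1] * h])
        M = np.eye(3)
        M[:2, :2] = R
        M[:2, 2] = t
        img = warp(img.astype(np.float64), AffineTransform(matrix=np.linalg.inv(M)),
                   order=1, cval=0.0, preserve_range=True)
    if img.shape[0] != out_size:
        img = resize(img, (out_size, out_size), order=1, anti_aliasing=False,
                     preserve_range=True)
    return img.astype(np.float32)


def sample_augmentation_params(rng: np.random.Generator
                               ) -> tuple[bool, float, tuple[float, float]]:
    """Draw one augmentation: flip ~ Bernoulli(1/2), rotation ~ U(-36, 36)
    degrees, width/height translation ~ U(-10%, +10%) each."""
    flip = bool(rng.random() < 0.5)
    rot = float(rng.uniform(-36.0, 36.0))
    tx = float(rng.uniform(-0.10, 0.10))
    ty = float(rng.uniform(-0.10, 0.10))
    return flip, rot, (tx, ty)


def augment_image(image: FundusImage | np.ndarray, rng: np.random.Generator,
                  out_size: int = 64) -> np.ndarray:
    """Random horizontal flip, rotation U(-36, 36) degrees, and width/height
    translation U(-10%, +10%), then bilinear resize to the backbone input."""
    px = image.pixels if isinstance(image, FundusImage) else image
    flip, rot, t = sample_augmentation_params(rng)
    return apply_augmentation(px, flip, rot, t, out_size)


# ---------------------------------------------------------------------------
# model


def default_head_configs(feature_dim: int) -> list[BinaryHeadConfig]:
    w1 = max(8, feature_dim // 2)
    widths = (w1, max(8, w1 // 2), max(8, w1 // 4))
    return [BinaryHeadConfig(task=t, fc_widths=widths) for t in HEAD_TASKS]


class ScreeningModel:
    """Backbone + 7 binary heads + soft-target fusion layer."""

    def __init__(self, backbone_cfg: BackboneConfig,
                 head_cfgs: Sequence[BinaryHeadConfig], seed: int = 0):
        if len(head_cfgs) != 7:
            raise ValueError("exactly 7 binary heads required (1 main + 6 pairwise)")
        for cfg, task in zip(head_cfgs, HEAD_TASKS):
            if tuple(cfg.task) != task:
                raise ValueError(f"head task order must follow {HEAD_TASKS}")
        self.backbone_cfg = backbone_cfg
        self.head_cfgs = list(head_cfgs)
        rng = np.random.default_rng(seed)
        convs = backbone_cfg.convs_per_block or tuple(
            1 for _ in backbone_cfg.block_widths)
        layers: list[nn.Layer] = []
        c_in = 3
        for width, n_conv in zip(backbone_cfg.block_widths, convs):
            for _ in range(n_conv):
                layers += [nn.Conv2d(c_in, width, rng=rng), nn.ReLU()]
                c_in = width
            layers.append(nn.MaxPool2d())
        self.backbone = nn.Sequential(layers)
        self.gap = nn.GlobalAvgPool()
        fdim = backbone_cfg.feature_map_shape[2]
        self.heads: list[nn.Sequential] = []
        for cfg in self.head_cfgs:
            h: list[nn.Layer] = []
            d = fdim
            for wdt in cfg.fc_widths:
                h += [nn.Dense(d, wdt, rng=rng), nn.ReLU(),
                      nn.Dropout(cfg.dropout_rate, rng=np.random.default_rng(
                          rng.integers(2**31)))]
                d = wdt
            h.append(nn.Dense(d, 2, rng=rng))
            self.heads.append(nn.Sequential(h))
        self.fusion = nn.Dense(14, len(CLASSES), rng=rng)
        self.soft_target_order = [f"{a}|{b}" for a, b in HEAD_TASKS]
        if backbone_cfg.pretrained_init is not None:
            backbone_cfg.pretrained_init(self)

    # -- forward passes -----------------------------------------------------

    def features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Last-convolutional-block feature map, NHWC."""
        self._check_input(x)
        return self.backbone.forward(x.astype(np.float32), train=train)

    def _check_input(self, x: np.ndarray) -> None:
        s = self.backbone_cfg.input_size
        if x.ndim != 4 or x.shape[1] != s or x.shape[2] != s or x.shape[3] != 3:
            raise ValueError(
                f"expected input batch of shape (N, {s}, {s}, 3), got {x.shape}")

    def head_probs_from_features(self, fvec: np.ndarray, head: int,
                                 train: bool = False) -> np.ndarray:
        return nn.softmax(self.heads[head].forward(fvec, train=train))

    def soft_targets_from_features(self, fvec: np.ndarray) -> np.ndarray:
        """Concatenated 7x2 softmax outputs, main head first (length 14)."""
        return np.concatenate(
            [self.head_probs_from_features(fvec, i) for i in range(7)], axis=1)

    def forward(self, x: np.ndarray) -> dict[str, np.ndarray]:
        fmap = self.features(x, train=False)
        fvec = self.gap.forward(fmap)
        st = self.soft_targets_from_features(fvec)
        probs = nn.softmax(self.fusion.forward(st))
        return {"feature_map": fmap, "features": fvec,
                "soft_targets": st, "class_probs": probs}

    def head_score_and_gradient(self, image: np.ndarray, head: int = 0,
                                class_idx: int = 0
                                ) -> tuple[np.ndarray, float, np.ndarray]:
        """For one image: last-conv feature map A, the head's pre-softmax
        class score S, and dS/dA (same shape as A). This is the gradient
        source for the class-activation mapping."""
        x = image[None] if image.ndim == 3 else image
        fmap = self.features(x, train=False)
        fvec = self.gap.forward(fmap)
        logits = self.heads[head].forward(fvec, train=False)
        score = float(logits[0, class_idx])
        dlogits = np.zeros_like(logits)
        dlogits[0, class_idx] = 1.0
        dfvec = self.heads[head].backward(dlogits)
        dA = self.gap.backward(dfvec)
        return fmap[0], score, dA[0]

    # -- bookkeeping ---------------------------------------------------------

    def parameter_groups(self) -> dict[str, list[np.ndarray]]:
        g = {"backbone": self.backbone.params(), "fusion": self.fusion.params()}
        for i in range(7):
            g[f"head{i}"] = self.heads[i].params()
        return g

    def parameter_count(self) -> int:
        return sum(p.size for ps in self.parameter_groups().values() for p in ps)

    def weights_checksum(self, groups: Sequence[str]) -> str:
        h = hashlib.sha256()
        for gname in groups:
            for p in self.parameter_groups()[gname]:
                h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    def save(self, path: str | Path) -> None:
        """Single-file checkpoint: weights + config + soft-target ordering."""
        buf = io.BytesIO()
        arrays = {}
        for gname, ps in self.parameter_groups().items():
            for i, p in enumerate(ps):
                arrays[f"{gname}_{i}"] = p
        np.savez(buf, **arrays)
        meta = {
            "backbone": {"input_size": self.backbone_cfg.input_size,
                         "block_widths": list(self.backbone_cfg.block_widths),
                         "convs_per_block": list(
                             self.backbone_cfg.convs_per_block or [])},
            "heads": [{"task": list(c.task), "fc_widths": list(c.fc_widths),
                       "dropout_rate": c.dropout_rate} for c in self.head_cfgs],
            "soft_target_order": self.soft_target_order,
            "classes": list(CLASSES),
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("weights.npz", buf.getvalue())
            zf.writestr("config.json", json.dumps(meta, indent=1, sort_keys=True))

    @staticmethod
    def load(path: str | Path) -> "ScreeningModel":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("config.json"))
            npz = np.load(io.BytesIO(zf.read("weights.npz")))
            bc = meta["backbone"]
            model = ScreeningModel(
                BackboneConfig(input_size=bc["input_size"],
                               block_widths=tuple(bc["block_widths"]),
                               convs_per_block=tuple(bc["convs_per_block"]) or None),
                [BinaryHeadConfig(task=tuple(h["task"]),
                                  fc_widths=tuple(h["fc_widths"]),
                                  dropout_rate=h["dropout_rate"])
                 for h in meta["heads"]])
            for gname, ps in model.parameter_groups().items():
                for i, p in enumerate(ps):
                    p[...] = npz[f"{gname}_{i}"]
        return model


def build_screening_model(backbone: BackboneConfig,
                          heads: Sequence[BinaryHeadConfig] | None = None,
                          seed: int = 0) -> ScreeningModel:
    if heads is None:
        heads = default_head_configs(backbone.feature_map_shape[2])
    return ScreeningModel(backbone, heads, seed=seed)


# ---------------------------------------------------------------------------
# training


def _augmented_pool(images: list[np.ndarray], labels: list[str],
                    per_class: int, out_size: int,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Fixed augmented training pool: ``per_class`` images per class, sampled
    with replacement and independently augmented."""
    by_class: dict[str, list[int]] = {c: [] for c in CLASSES}
    for i, lab in enumerate(labels):
        by_class[lab].append(i)
    xs, ys = [], []
    for ci, cls in enumerate(CLASSES):
        idxs = by_class[cls]
        if not idxs:
            continue
        picks = rng.choice(idxs, size=per_class, replace=True)
        for j in picks:
            xs.append(augment_image(images[j], rng, out_size=out_size))
            ys.append(ci)
    order = rng.permutation(len(xs))
    return np.stack(xs)[order], np.asarray(ys)[order]


def _minibatches(n: int, batch: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch):
        yield order[i:i + batch]


def _train_mlp(head: nn.Sequential, X: np.ndarray, y: np.ndarray,
               Xv: np.ndarray, yv: np.ndarray, cfg: TrainConfig,
               max_epochs: int, log: TrainingLog, step_name: str,
               rng: np.random.Generator) -> None:
    """Train a small FC head (or fusion layer) with Adam + plateau schedule."""
    opt = nn.Adam(head.params(), lr=cfg.lr_init)
    sched = nn.PlateauScheduler(opt, cfg.lr_decay_factor, cfg.patience_epochs,
                                cfg.lr_floor)
    best, stale = np.inf, 0
    for epoch in range(max_epochs):
        losses = []
        for bidx in _minibatches(len(X), cfg.batch_size, rng):
            probs = nn.softmax(head.forward(X[bidx], train=True))
            loss, dlogits = nn.cross_entropy(probs, y[bidx])
            head.backward(dlogits)
            opt.step(head.grads())
            losses.append(loss)
        vp = nn.softmax(head.forward(Xv, train=False))
        vloss, _ = nn.cross_entropy(vp, yv)
        log.add(step_name, epoch, np.mean(losses), vloss, opt.lr)
        sched.step(vloss)
        if vloss < best - 1e-5:
            best, stale = vloss, 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break


def _train_backbone_main(model: ScreeningModel, X: np.ndarray, y01: np.ndarray,
                         Xv: np.ndarray, yv01: np.ndarray, cfg: TrainConfig,
                         log: TrainingLog, rng: np.random.Generator) -> None:
    """Step 1: joint backbone + main-head training on retinopathy vs HC."""
    params = model.backbone.params() + model.heads[0].params()
    opt = nn.Adam(params, lr=cfg.lr_init)
    sched = nn.PlateauScheduler(opt, cfg.lr_decay_factor, cfg.patience_epochs,
                                cfg.lr_floor)
    best, stale = np.inf, 0
    for epoch in range(cfg.max_epochs_backbone):
        losses = []
        for bidx in _minibatches(len(X), cfg.batch_size, rng):
            fmap = model.backbone.forward(X[bidx], train=True)
            fvec = model.gap.forward(fmap)
            logits = model.heads[0].forward(fvec, train=True)
            probs = nn.softmax(logits)
            loss, dlogits = nn.cross_entropy(probs, y01[bidx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at step 1 epoch {epoch}")
            dfvec = model.heads[0].backward(dlogits)
            dfmap = model.gap.backward(dfvec)
            model.backbone.backward(dfmap)
            opt.step(model.backbone.grads() + model.heads[0].grads())
            losses.append(loss)
        # validation in inference mode, batched to bound memory
        vlosses = []
        for i in range(0, len(Xv), 128):
            fv = model.gap.forward(model.backbone.forward(Xv[i:i + 128]))
            vp = nn.softmax(model.heads[0].forward(fv))
            vl, _ = nn.cross_entropy(vp, yv01[i:i + 128])
            vlosses.append(vl * len(fv))
        vloss = float(np.sum(vlosses) / len(Xv))
        log.add("step1_backbone_main", epoch, np.mean(losses), vloss, opt.lr)
        sched.step(vloss)
        if vloss < best - 1e-5:
            best, stale = vloss, 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break


def _batched_features(model: ScreeningModel, X: np.ndarray,
                      batch: int = 128) -> np.ndarray:
    out = []
    for i in range(0, len(X), batch):
        out.append(model.gap.forward(model.backbone.forward(X[i:i + batch])))
    return np.concatenate(out, axis=0)


def train_three_step(dataset: LabeledDataset, cfg: TrainConfig,
                     backbone_cfg: BackboneConfig | None = None,
                     train_idx: np.ndarray | None = None,
                     ) -> tuple[ScreeningModel, TrainingLog]:
    """Three-step training protocol on a labeled cohort.

    Step 1 trains the feature extractor jointly with the main retinopathy-vs-HC
    head; step 2 trains the six pairwise heads on the (frozen) extractor's
    pooled features; step 3 trains only the fusion layer on the concatenated
    soft-target vectors. Validation images are held out grouped by eye.
    """
    backbone_cfg = backbone_cfg or BackboneConfig()
    if train_idx is None:
        train_idx = np.arange(len(dataset))
    labels = [dataset.labels[i] for i in train_idx]
    missing = set(CLASSES) - set(labels)
    if missing:
        raise ValueError(f"training split lacks classes: {sorted(missing)}")

    rng = np.random.default_rng(cfg.rng_seed)
    # grouped validation split inside the training indices
    eyes = [dataset.eye_ids[i] for i in train_idx]
    uniq = sorted(set(eyes))
    eye_label = {e: labels[eyes.index(e)] for e in uniq}
    val_eyes: set[str] = set()
    for cls in CLASSES:
        ce = [e for e in uniq if eye_label[e] == cls]
        n_val = max(1, int(round(cfg.val_frac * len(ce))))
        val_eyes.update(rng.permutation(ce)[:n_val].tolist())
    tr_mask = np.array([e not in val_eyes for e in eyes])
    tr_imgs = [dataset.images[i].pixels for i, m in zip(train_idx, tr_mask) if m]
    tr_labs = [lab for lab, m in zip(labels, tr_mask) if m]
    va_imgs = [dataset.images[i].pixels for i, m in zip(train_idx, tr_mask) if not m]
    va_labs = [lab for lab, m in zip(labels, tr_mask) if not m]

    size = backbone_cfg.input_size
    X, y = _augmented_pool(tr_imgs, tr_labs, cfg.per_class_augmented_count,
                           size, rng)
    n_val_aug = max(20, cfg.per_class_augmented_count // 5)
    Xv, yv = _augmented_pool(va_imgs, va_labs, n_val_aug, size, rng)

    model = build_screening_model(backbone_cfg, seed=cfg.rng_seed)
    log = TrainingLog()

    # step 1 — main head; output convention: index 0 = retinopathy, 1 = HC
    # (each head's softmax index order follows its (class_a, class_b) task)
    hc = CLASSES.index("HC")
    _train_backbone_main(model, X, (y == hc).astype(int),
                         Xv, (yv == hc).astype(int), cfg, log, rng)

    # step 2 — pairwise heads on frozen-backbone features
    F = _batched_features(model, X)
    Fv = _batched_features(model, Xv)
    for h, (a, b) in enumerate(HEAD_TASKS[1:], start=1):
        ia, ib = CLASSES.index(a), CLASSES.index(b)
        sel = np.isin(y, [ia, ib])
        selv = np.isin(yv, [ia, ib])
        _train_mlp(model.heads[h], F[sel], (y[sel] == ib).astype(int),
                   Fv[selv], (yv[selv] == ib).astype(int), cfg,
                   cfg.max_epochs_heads, log, f"step2_head{h}_{a}v{b}", rng)

    # step 3 — fusion layer only, on soft targets
    ST = np.concatenate([nn.softmax(model.heads[i].forward(F))
                         for i in range(7)], axis=1)
    STv = np.concatenate([nn.softmax(model.heads[i].forward(Fv))
                          for i in range(7)], axis=1)
    fusion_seq = nn.Sequential([model.fusion])
    _train_mlp(fusion_seq, ST, y, STv, yv, cfg, cfg.max_epochs_fusion,
               log, "step3_fusion", rng)
    return model, log


# ---------------------------------------------------------------------------
# inference and voting


def predict_images(model: ScreeningModel, images: Sequence[FundusImage] | np.ndarray,
                   batch: int = 64) -> dict[str, np.ndarray | list[str]]:
    """Deterministic inference: soft-target vectors, 5-class probabilities,
    and argmax labels. Inputs must already be at the backbone input size
    (no silent resize)."""
    if isinstance(images, np.ndarray):
        X = images
    else:
        X = np.stack([im.pixels for im in images])
    model._check_input(X)
    sts, probs = [], []
    for i in range(0, len(X), batch):
        out = model.forward(X[i:i + batch])
        sts.append(out["soft_targets"])
        probs.append(out["class_probs"])
    st = np.concatenate(sts)
    pr = np.concatenate(probs)
    labels = [CLASSES[int(k)] for k in pr.argmax(axis=1)]
    return {"soft_targets": st, "class_probs": pr, "labels": labels}


def vote_patient(image_labels: Sequence[str],
                 image_scores: np.ndarray | None = None,
                 patient_id: str = "P000") -> PatientPrediction:
    """Majority vote over a patient's per-image labels; ties are broken by the
    highest mean class probability across the patient's images."""
    if len(image_labels) == 0:
        raise ValueError("cannot vote on an empty image list")
    counts: dict[str, int] = {}
    for lab in image_labels:
        counts[lab] = counts.get(lab, 0) + 1
    top = max(counts.values())
    tied = sorted(c for c, n in counts.items() if n == top)
    if len(tied) == 1 or image_scores is None:
        winner = tied[0]
    else:
        means = np.asarray(image_scores).mean(axis=0)
        winner = max(tied, key=lambda c: means[CLASSES.index(c)])
    return PatientPrediction(patient_id, list(image_labels), winner, counts)


# ---------------------------------------------------------------------------
# nested cross-validation


@dataclass
class CVFold:
    train_eyes: list[str]
    test_eyes: list[str]
    train_idx: np.ndarray
    test_idx: np.ndarray


def _partition_eyes(dataset: LabeledDataset, eyes: list[str], k: int,
                    rng: np.random.Generator) -> list[list[str]]:
    """Class-stratified partition of eyes into k groups."""
    eye_label = {e: dataset.labels[dataset.eye_ids.index(e)] for e in eyes}
    groups: list[list[str]] = [[] for _ in range(k)]
    for cls in sorted(set(eye_label.values())):
        ce = list(rng.permutation([e for e in eyes if eye_label[e] == cls]))
        if len(ce) < k:
            raise ValueError(f"class {cls} has {len(ce)} eyes < {k} folds")
        for i, e in enumerate(ce):
            groups[i % k].append(e)
    return groups


def nested_cv_folds(dataset: LabeledDataset, outer_k: int = 5,
                    inner_k: int = 5, seed: int = 0
                    ) -> list[tuple[CVFold, list[CVFold]]]:
    """Grouped, class-stratified nested folds: the outer test folds are
    pairwise disjoint and cover all eyes; no eye ever appears in both the
    train and test side of any (outer or inner) fold."""
    rng = np.random.default_rng(seed)
    eyes = sorted(set(dataset.eye_ids))
    eye_arr = np.asarray(dataset.eye_ids)
    outer_groups = _partition_eyes(dataset, eyes, outer_k, rng)

    def fold_from(train_e: list[str], test_e: list[str]) -> CVFold:
        return CVFold(sorted(train_e), sorted(test_e),
                      np.flatnonzero(np.isin(eye_arr, train_e)),
                      np.flatnonzero(np.isin(eye_arr, test_e)))

    out = []
    for i in range(outer_k):
        test_e = outer_groups[i]
        train_e = [e for g in outer_groups[:i] + outer_groups[i + 1:] for e in g]
        inner_groups = _partition_eyes(dataset, train_e, inner_k, rng)
        inner = []
        for j in range(inner_k):
            ival = inner_groups[j]
            itr = [e for g in inner_groups[:j] + inner_groups[j + 1:] for e in g]
            inner.append(fold_from(itr, ival))
        out.append((fold_from(train_e, test_e), inner))
    return out


def format_mean_sd(values: Sequence[float], digits: int = 3) -> str:
    v = np.asarray(values, dtype=float)
    return f"{v.mean():.2f}±{v.std(ddof=1):.{digits}f}"


def nested_cv(dataset: LabeledDataset, cfg: TrainConfig,
              outer_k: int = 5, inner_k: int = 5,
              trainer: Callable | None = None,
              ) -> dict:
    """Run the nested-CV protocol: for each outer fold, train on the outer
    train eyes (the inner folds are exposed for tuning) and evaluate on the
    outer test eyes. ``trainer(dataset, train_idx, cfg) -> predict_fn`` may be
    substituted (e.g. a fast baseline) to exercise the machinery; the default
    is the full three-step trainer."""
    from .metrics import compute_metrics

    folds = nested_cv_folds(dataset, outer_k, inner_k, seed=cfg.rng_seed)

    def default_trainer(ds, tr_idx, c):
        model, _ = train_three_step(ds, c, train_idx=tr_idx)
        size = model.backbone_cfg.input_size

        def predict(idx):
            X = np.stack([resize(ds.images[i].pixels, (size, size), order=1,
                                 preserve_range=True).astype(np.float32)
                          for i in idx])
            return predict_images(model, X)
        return predict

    trainer = trainer or default_trainer
    per_fold = []
    for outer, _inner in folds:
        predict = trainer(dataset, outer.train_idx, cfg)
        res = predict(outer.test_idx)
        y_true = [dataset.labels[i] for i in outer.test_idx]
        mt = compute_metrics(y_true, res["labels"], res["class_probs"],
                             classes=CLASSES)
        per_fold.append(mt)
    summary = {}
    for key in ("accuracy", "precision", "sensitivity", "specificity",
                "f1", "auc", "kappa"):
        vals = [f.macro[key] for f in per_fold if np.isfinite(f.macro[key])]
        summary[key] = {"mean": float(np.mean(vals)),
                        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                        "formatted": format_mean_sd(vals) if len(vals) > 1
                        else f"{np.mean(vals):.2f}"}
    return {"folds": folds, "fold_metrics": per_fold, "summary": summary}
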