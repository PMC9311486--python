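"""Grad-CAM++ abnormality heatmaps from the last convolutional layer.

The heatmap for a target class is a rectified weighted sum of the last
convolutional feature-map channels. Channel weights come from the Grad-CAM++
closed form for an exponential of the class score: with g = dS/dA the plain
gradient of the pre-softmax class score S with respect to activations A, the
per-location weighting coefficients are

    alpha_ij^k = g_ij^2 / (2 g_ij^2 + sum_ab A_ab^k g_ij^3)

(the exp(S) factors cancel), the channel weight is w_k = sum_ij alpha_ij^k
relu(g_ij), and the raw map is relu(sum_k w_k A^k). This uses first-order
gradients only — the higher-order terms reduce to elementwise powers of g —
which is the numerically standard implementation and directly checkable
against a finite-difference oracle.

The default target is the main head's "retinopathy" class; per-disease-head
maps are available via ``head``/``class_idx``. Post-processing follows the
display pipeline: bilinear upsampling to 512x512 and min-max normalization
to [0, 1] (a constant raw map normalizes to all zeros).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize

from .screening import ScreeningModel

#: index of the "retinopathy" output within the main head's 2-way softmax
#: (ordering: [HC, retinopathy] — class b of the ("retinopathy", "HC") task
#: is HC at index 1, so retinopathy is index 0)
RETINOPATHY_CLASS = 0


@dataclass
class Heatmap:
    """Nonnegative scalar map over pixels; processed maps live in [0, 1]."""

    values: np.ndarray
    source_image_id: str = ""
    target_class: str = "retinopathy"
    processed: bool = False

    @property
    def mean(self) -> float:
        """E(H): mean intensity."""
        return float(self.values.mean())

    @property
    def sd(self) -> float:
        """sigma: population standard deviation of intensity."""
        return float(self.values.std())


def gradcam_pp(model: ScreeningModel, image: np.ndarray, head: int = 0,
               class_idx: int = RETINOPATHY_CLASS,
               image_id: str = "") -> Heatmap:
    """Raw Grad-CAM++ map at the last-conv spatial resolution.

    All-zero gradients produce an all-zero map (not an error).
    """
    n_out = 2
    if not (0 <= class_idx < n_out):
        raise IndexError(f"class index {class_idx} out of range for a binary head")
    if not (0 <= head < len(model.heads)):
        raise IndexError(f"head index {head} out of range")
    A, _score, g = model.head_score_and_gradient(image, head=head,
                                                 class_idx=class_idx)
    A = A.astype(np.float64)
    g = g.astype(np.float64)
    g2 = g * g
    g3 = g2 * g
    chan_sum = A.sum(axis=(0, 1), keepdims=True)  # sum_ab A^k
    denom = 2.0 * g2 + chan_sum * g3
    alpha = np.where(np.abs(denom) > 1e-12, g2 / np.where(denom == 0, 1, denom), 0.0)
    weights = (alpha * np.maximum(g, 0.0)).sum(axis=(0, 1))  # (C,)
    raw = np.maximum((A * weights).sum(axis=2), 0.0)
    task = model.head_cfgs[head].task
    return Heatmap(values=raw, source_image_id=image_id,
                   target_class=task[class_idx] if head == 0 else
                   f"{task[0]}|{task[1]}[{class_idx}]")


def postprocess_heatmap(raw: Heatmap, out_size: int = 512) -> Heatmap:
    """Bilinear upsample to the display resolution, then min-max normalize to
    [0, 1]. A constant raw map maps to all zeros (degenerate rule)."""
    v = np.asarray(raw.values, dtype=np.float64)
    if (v < 0).any():
        raise ValueError("raw heatmap must be nonnegative")
    up = resize(v, (out_size, out_size), order=1, anti_aliasing=False,
                preserve_range=True)
    lo, hi = up.min(), up.max()
    if hi - lo < 1e-15:
        norm = np.zeros_like(up)
    else:
        norm = (up - lo) / (hi - lo)
    return Heatmap(values=norm, source_image_id=raw.source_image_id,
                   target_class=raw.target_class, processed=True)


_JET = None


def _jet_colormap(values: np.ndarray) -> np.ndarray:
    global _JET
    if _JET is None:
        from matplotlib import colormaps
        _JET = colormaps["jet"]
    return _JET(np.clip(values, 0, 1))[..., :3]


def overlay(image: np.ndarray, heatmap: Heatmap, alpha: float = 0.4) -> np.ndarray:
    """Colormapped heatmap alpha-blended onto the image:
    out = (1 - alpha) * image + alpha * colormap(heatmap)."""
    hv = heatmap.values
    if image.shape[:2] != hv.shape:
        raise ValueError(f"geometry mismatch: image {image.shape[:2]} "
                         f"vs heatmap {hv.shape}")
    color = _jet_colormap(hv)
    return ((1.0 - alpha) * image.astype(np.float64) + alpha * color).astype(
        np.float64)


def save_heatmap(h: Heatmap, path_png: str | Path,
                 path_raw: str | Path | None = None) -> None:
    """16-bit PNG of the map; optional .npy of the raw values."""
    arr = np.clip(h.values, 0, 1) if h.processed else \
        h.values / (h.values.max() + 1e-12)
    Image.fromarray((arr * 65535).astype(np.uint16)).save(str(path_png))
    if path_raw is not None:
        np.save(str(path_raw), h.values)
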