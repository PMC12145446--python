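"""Attention extraction and heatmap overlays for the image encoder.

The CLS token's attention over patch tokens says which parts of a brightfield
frame drove the image representation. Attention is aggregated across heads by
the mean and across layers by attention rollout — multiplying the
residual-corrected per-layer matrices (A + I)/2 (rows renormalized) — then the
CLS-to-patch row is reshaped to the patch grid, bilinearly upsampled to the
frame size and min-max normalized to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = ["AttentionMap", "attention_map", "overlay_heatmap"]


@dataclass
class AttentionMap:
    """Per-layer attention plus the aggregated CLS-to-patch heat image."""

    layer_attention: np.ndarray  # (L, heads, N+1, N+1)
    grid: np.ndarray  # (H/P, W/P) aggregated CLS-to-patch weights
    heat: np.ndarray  # (H, W) upsampled, min-max normalized to [0, 1]


def _rollout(layers: np.ndarray) -> np.ndarray:
    """Attention rollout: product over layers of row-normalized (A + I)/2."""
    n = layers.shape[-1]
    result = np.eye(n)
    for att in layers:  # layer order: first applied first
        a = att.mean(axis=0)  # head mean
        a = 0.5 * (a + np.eye(n))
        a = a / a.sum(axis=-1, keepdims=True)
        result = a @ result
    return result


def attention_map(model, image: np.ndarray, method: str = "rollout") -> AttentionMap:
    """Extract the aggregated attention heatmap of one preprocessed image.

    `model` is an :class:`~dilitracer.stvit_model.STViT` (or a fitted
    estimator exposing ``model_``). ``method="rollout"`` (default) aggregates
    across layers; ``"last"`` uses only the final layer's head-mean.
    """
    from ._autograd import no_grad

    net = getattr(model, "model_", model)
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError(f"expected one (H, W, C) image, got shape {image.shape}")
    with no_grad():
        _, layers = net.encode_image(image, return_attention=True)
    layers = np.asarray(layers)  # (L, heads, N+1, N+1)
    if method == "rollout":
        agg = _rollout(layers)
    elif method == "last":
        a = layers[-1].mean(axis=0)
        agg = a / a.sum(axis=-1, keepdims=True)
    else:
        raise ValueError(f"unknown aggregation method {method!r}")
    cls_to_patch = agg[0, 1:]  # CLS row, patch columns
    g = net.cfg.grid_size
    grid = cls_to_patch.reshape(g, g)
    heat = _sk_resize(grid, image.shape[:2], order=1, anti_aliasing=False, preserve_range=True)
    lo, hi = heat.min(), heat.max()
    heat = (heat - lo) / (hi - lo) if hi > lo else np.zeros_like(heat)
    return AttentionMap(layer_attention=layers, grid=grid, heat=heat)


def overlay_heatmap(
    image: np.ndarray,
    amap: "AttentionMap | np.ndarray",
    out_path: str | Path | None = None,
    colormap: str = "jet",
    alpha: float = 0.5,
) -> np.ndarray:
    """Alpha-blend the colormapped heatmap over the brightfield frame.

    `image` is (H, W) grayscale in [0, 1] or an (H, W, 3) RGB/preprocessed
    frame; standardized inputs are mapped back to [0, 1] for display. Returns
    the uint8 RGB overlay and, when `out_path` is given, writes a PNG
    (deterministic bytes for identical inputs).
    """
    import matplotlib

    heat = amap.heat if isinstance(amap, AttentionMap) else np.asarray(amap)
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = np.repeat(img[:, :, None], 3, axis=2)
    if img.shape[:2] != heat.shape:
        raise ValueError(f"image {img.shape[:2]} and heatmap {heat.shape} frames differ")
    if img.min() < 0:  # undo [-1, 1] standardization for display
        img = img * 0.5 + 0.5
    img = np.clip(img, 0.0, 1.0)
    cmap = matplotlib.colormaps[colormap]
    colored = cmap(heat)[:, :, :3]
    blend = (1.0 - alpha) * img + alpha * colored
    out = np.round(blend * 255.0).astype(np.uint8)
    if out_path is not None:
        from PIL import Image

        Image.fromarray(out).save(Path(out_path), format="PNG")
    return out
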