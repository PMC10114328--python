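"""Activation visualization: the tool that motivated the stage-5 fusion.

Captures a named layer's activation tensor for one image, reduces it across
channels to a heatmap normalized to [0,1], optionally merges two layers'
features with any of the five elementwise operators, and alpha-blends the
colormapped heatmap over the input photograph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from PIL import Image

from .errors import ConfigError
from .revnet import FusionSpec, RevisedResNet50, images_to_batch, merge_features


@dataclass
class ActivationMap:
    values: np.ndarray  # (h, w) in [0, 1]
    layer_name: str


@dataclass
class OverlayConfig:
    reduction: str = "mean"
    alpha: float = 0.5
    cmap: str = "jet"

    def __post_init__(self):
        if not 0 <= self.alpha <= 1:
            raise ConfigError("alpha must be in [0, 1]")
        if self.reduction not in ("mean", "max"):
            raise ConfigError("reduction must be 'mean' or 'max'")


def layer_activation(
    model: RevisedResNet50, img: np.ndarray, layer_name: str
) -> np.ndarray:
    """Forward the image and return the (h, w, c) activation at a named layer."""
    _, acts = model.forward(images_to_batch([img]))
    available = [k for k in acts if k.endswith("_out")]
    if layer_name not in acts:
        raise ConfigError(
            f"unknown layer {layer_name!r}; available: {', '.join(available)}"
        )
    return np.ascontiguousarray(acts[layer_name].data[0].transpose(1, 2, 0))


def to_heatmap(
    tensor: np.ndarray, reduction: str = "mean", layer_name: str = ""
) -> ActivationMap:
    """Reduce channels (mean or max) and min-max normalize to [0, 1].

    A constant map normalizes to all zeros rather than dividing by zero.
    """
    t = np.asarray(tensor, dtype=np.float64)
    if t.ndim == 2:
        t = t[:, :, None]
    reduced = t.mean(axis=2) if reduction == "mean" else t.max(axis=2)
    lo, hi = reduced.min(), reduced.max()
    if hi - lo < 1e-12:
        values = np.zeros_like(reduced)
    else:
        values = (reduced - lo) / (hi - lo)
    return ActivationMap(values=values, layer_name=layer_name)


def merged_heatmap(
    model: RevisedResNet50,
    img: np.ndarray,
    fusion: FusionSpec,
    reduction: str = "mean",
) -> ActivationMap:
    """Heatmap of the elementwise merge of two tapped layers."""
    a = layer_activation(model, img, fusion.layer_a)
    b = layer_activation(model, img, fusion.layer_b)
    merged = merge_features(a, b, fusion.merge_op)
    return to_heatmap(
        merged,
        reduction,
        layer_name=f"{fusion.layer_a} {fusion.merge_op} {fusion.layer_b}",
    )


def overlay(
    img: np.ndarray, amap: ActivationMap, cfg: OverlayConfig = OverlayConfig()
) -> np.ndarray:
    """Blend the colormapped heatmap over the image; alpha 0 is the identity."""
    img = np.asarray(img, dtype=np.uint8)
    if cfg.alpha == 0:
        return img.copy()
    h, w = img.shape[:2]
    up = np.asarray(
        Image.fromarray((amap.values * 255).astype(np.uint8)).resize(
            (w, h), Image.BILINEAR
        ),
        dtype=np.float64,
    ) / 255.0
    heat = (colormaps[cfg.cmap](up)[:, :, :3] * 255.0)
    blended = (1 - cfg.alpha) * img.astype(np.float64) + cfg.alpha * heat
    return np.clip(np.round(blended), 0, 255).astype(np.uint8)


def render_merge_panels(
    model: RevisedResNet50,
    img: np.ndarray,
    out_path: str,
    ops: tuple[str, ...] = ("addition", "average", "maximum", "multiplication", "subtraction"),
    reduction: str = "mean",
    alpha: float = 0.5,
) -> None:
    """Write a side-by-side figure of the merged heatmaps for each operator."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cfg = OverlayConfig(reduction=reduction, alpha=alpha)
    fig, axes = plt.subplots(1, len(ops) + 1, figsize=(3 * (len(ops) + 1), 3.2))
    axes[0].imshow(img)
    axes[0].set_title("input")
    for ax, op in zip(axes[1:], ops):
        amap = merged_heatmap(model, img, FusionSpec(merge_op=op), reduction)
        ax.imshow(overlay(img, amap, cfg))
        ax.set_title(op)
    for ax in axes:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
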