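"""Gradient-weighted class activation mapping over the VGG-style blocks.

For a chosen block (2..5) the class score's gradient on that block's last
convolutional activation is averaged spatially to give one importance
weight per channel; the weighted channel sum is rectified (negative
evidence is outside Grad-CAM's semantics), bilinearly upsampled to the
input size and normalized to max 1 (an identically zero map stays zero).

Per-class aggregation averages per-map-normalized heatmaps over many
(correctly classified, identically oriented) images, and the "major
impact" region is the set of pixels above a fraction (default 0.75) of
the map maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, transform

from .classify import TrainedClassifier

__all__ = [
    "Heatmap",
    "gradcam",
    "aggregate_heatmaps",
    "major_impact_region",
    "overlay",
]

VALID_BLOCKS = (2, 3, 4, 5)


@dataclass
class Heatmap:
    values: np.ndarray          # (S, S) in [0, 1]; max 1 unless all-zero
    source_block: int
    target_class: int

    def validate(self) -> None:
        assert (self.values >= 0).all()
        m = self.values.max()
        assert np.isclose(m, 1.0) or m == 0.0


def _normalize(values: np.ndarray) -> np.ndarray:
    m = values.max()
    return values / m if m > 0 else values


def gradcam(model: TrainedClassifier, image: np.ndarray, target_class: int,
            block: int) -> Heatmap:
    """Grad-CAM heatmap of ``target_class`` at the given block.

    ``image`` is a (3, S, S) array (or an EggImage, whose image is
    transposed automatically).  The class score is the pre-softmax logit.
    """
    if block not in VALID_BLOCKS:
        raise ValueError(f"unknown block {block}; valid blocks: {VALID_BLOCKS}")
    if hasattr(image, "image"):
        image = np.transpose(image.image, (2, 0, 1))
    x = np.asarray(image, dtype=model.net.params()[0].dtype)[None]
    size = x.shape[-1]

    layer_idx = model.block_ends[block]
    n_out = model.n_classes
    onehot = np.zeros((1, n_out), dtype=x.dtype)
    onehot[0, target_class] = 1.0
    acts, grads = model.net.activation_grad(model.prep(x), layer_idx, onehot)

    weights = grads[0].mean(axis=(1, 2))               # (C,)
    cam = np.einsum("c,chw->hw", weights, acts[0])
    cam = np.maximum(cam, 0.0)                          # rectify
    cam = transform.resize(cam, (size, size), order=1, anti_aliasing=False,
                           preserve_range=True)
    cam = np.maximum(cam, 0.0)
    return Heatmap(values=_normalize(cam.astype(np.float64)),
                   source_block=block, target_class=target_class)


def aggregate_heatmaps(heatmaps: list[Heatmap]) -> Heatmap:
    """Pixelwise mean of per-map-normalized heatmaps, renormalized.

    All maps must share size, source block and target class.
    """
    if not heatmaps:
        raise ValueError("cannot aggregate an empty list of heatmaps")
    first = heatmaps[0]
    for h in heatmaps[1:]:
        if (h.values.shape != first.values.shape
                or h.source_block != first.source_block
                or h.target_class != first.target_class):
            raise ValueError("heatmaps differ in size, block or class")
    stack = np.stack([_normalize(h.values) for h in heatmaps])
    return Heatmap(values=_normalize(stack.mean(axis=0)),
                   source_block=first.source_block,
                   target_class=first.target_class)


def major_impact_region(heatmap: Heatmap | np.ndarray,
                        fraction: float = 0.75
                        ) -> tuple[np.ndarray, list[np.ndarray]]:
    """Pixels above ``fraction`` of the map maximum, plus their contours.

    Returns (mask, contours); contours are (n, 2) arrays of (row, col)
    polyline vertices.  An all-zero map yields an empty mask.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    m = values.max()
    if m == 0:
        return np.zeros(values.shape, dtype=bool), []
    mask = values > fraction * m
    contours = measure.find_contours(mask.astype(float), 0.5)
    return mask, contours


def save_heatmap(heatmap: Heatmap, path) -> None:
    """Write a heatmap as an 8-bit PNG plus a lossless float sidecar."""
    from pathlib import Path

    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path.with_suffix(".png"),
                (np.clip(heatmap.values, 0, 1) * 255).round().astype(np.uint8))
    np.save(path.with_suffix(".npy"), heatmap.values)


def tiled_aggregate_figure(aggregates: dict, path) -> None:
    """Save a classes x blocks grid of aggregated heatmaps.

    ``aggregates`` maps (class_label, block) to a Heatmap.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    classes = sorted({c for c, _ in aggregates})
    blocks = sorted({b for _, b in aggregates})
    fig, axes = plt.subplots(len(classes), len(blocks),
                             figsize=(2.2 * len(blocks), 2.2 * len(classes)),
                             squeeze=False)
    for i, cls in enumerate(classes):
        for j, block in enumerate(blocks):
            ax = axes[i][j]
            ax.set_xticks([])
            ax.set_yticks([])
            heat = aggregates.get((cls, block))
            if heat is not None:
                ax.imshow(colormap(heat.values))
            if i == 0:
                ax.set_title(f"block {block}", fontsize=9)
            if j == 0:
                ax.set_ylabel(cls, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


_JET_ANCHORS = np.array([
    [0.0, 0.0, 0.5], [0.0, 0.0, 1.0], [0.0, 1.0, 1.0],
    [1.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.5, 0.0, 0.0]])


def colormap(values: np.ndarray) -> np.ndarray:
    """Map [0, 1] values through a jet-like colormap to RGB."""
    from matplotlib import cm

    return cm.jet(np.clip(values, 0, 1))[..., :3]


def overlay(image: np.ndarray, heatmap: Heatmap | np.ndarray,
            alpha: float = 0.5,
            contours: list[np.ndarray] | None = None,
            contour_color: tuple[float, float, float] = (1.0, 1.0, 0.0)
            ) -> np.ndarray:
    """Alpha-blend a colormapped heatmap over an RGB image.

    ``alpha`` 0 returns the image, 1 the pure colormapped heatmap.
    Optional contour polylines are rasterized on top in ``contour_color``.
    """
    if hasattr(image, "image"):
        image = image.image
    values = heatmap.values if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    if values.shape != image.shape[:2]:
        raise ValueError("image and heatmap sizes differ")
    colored = colormap(values)
    out = (1 - alpha) * np.asarray(image, dtype=np.float64) + alpha * colored
    if contours:
        for contour in contours:
            rr = np.clip(contour[:, 0].round().astype(int), 0, out.shape[0] - 1)
            cc = np.clip(contour[:, 1].round().astype(int), 0, out.shape[1] - 1)
            out[rr, cc] = contour_color
    return np.clip(out, 0.0, 1.0)
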