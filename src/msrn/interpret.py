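"""Grad-CAM heatmaps for single- and multi-branch SRN models.

Gradient-weighted class activation mapping: the gradient of one class
logit with respect to a convolutional feature map is global-average-pooled
into per-channel weights, the weighted channel sum is rectified, bilinearly
upsampled to the input size, and max-normalized to [0, 1].  The default
target layer is the last convolutional block's pre-pool activation map,
the highest-level spatial representation.

For a multi-scale model each branch gets its own heatmap, with gradients
flowing from the shared fused logit back through the feature concatenation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
from PIL import Image

from .architecture import MSSRN, SRN
from .training import resize_bilinear


@dataclass(frozen=True)
class Heatmap:
    values: np.ndarray  # (H, W) in [0, 1], input-sized
    class_index: int
    branch_index: int = 0

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise ValueError("heatmap must be 2-D")
        if v.size and (v.min() < 0 or v.max() > 1 + 1e-6):
            raise ValueError("heatmap values must lie in [0, 1]")


def _cam_from_capture(activation: np.ndarray, grad: np.ndarray,
                      out_side: int) -> np.ndarray:
    # channel weights: global average pool of the gradients
    weights = grad.mean(axis=(2, 3))  # (N=1, C)
    cam = np.einsum("nc,nchw->nhw", weights, activation)[0]
    cam = np.maximum(cam, 0.0)
    cam = resize_bilinear(cam.astype(np.float32), out_side)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return cam.astype(np.float32)


def grad_cam(model, image: np.ndarray, class_index: int,
             target_block: int = 5) -> Heatmap | list[Heatmap]:
    """Heatmap(s) for one image (or per-branch list of images for MS-SRN).

    ``image`` is (3, s, s) for an SRN, or a list of such arrays (one per
    branch) for an MSSRN.  ``target_block`` indexes the six blocks; the
    default is the last block's pre-pool activation.  A constant logit
    yields an all-zero map (not an error).
    """
    if isinstance(model, SRN):
        branches = [model]
        xs = [np.asarray(image)[None]]
    elif isinstance(model, MSSRN):
        branches = model.branches
        xs = [np.asarray(im)[None] for im in image]
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    if not 0 <= class_index < (model.config.num_classes):
        raise ValueError(f"class_index {class_index} out of range")

    captured = []
    for br in branches:
        block = br.blocks[target_block]
        block.capture = True
        captured.append(block)
    try:
        if isinstance(model, SRN):
            logits = model.forward(xs[0], train=True)
        else:
            logits = model.forward(xs, train=True)
        seed = np.zeros_like(logits)
        seed[:, class_index] = 1.0
        for p in model.params():
            p.grad[...] = 0
        model.backward(seed)
        maps = []
        for i, (block, x) in enumerate(zip(captured, xs)):
            cam = _cam_from_capture(block.activation, block.activation_grad,
                                    x.shape[-1])
            maps.append(Heatmap(values=cam, class_index=class_index,
                                branch_index=i))
    finally:
        for block in captured:
            block.capture = False
            block.activation = block.activation_grad = None
    return maps[0] if isinstance(model, SRN) else maps


def render_overlay(image: np.ndarray, heatmap: Heatmap, output_path,
                   alpha: float = 0.45, colormap: str = "jet") -> Path:
    """Write a color-mapped heatmap overlay PNG; deterministic."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 3:  # (C, H, W) -> grayscale
        img = img.mean(axis=0)
    if img.shape != heatmap.values.shape:
        raise ValueError("image and heatmap sizes differ")
    cmap = matplotlib.colormaps[colormap]
    colored = cmap(heatmap.values.astype(np.float64))[..., :3]
    base = np.repeat(img[..., None], 3, axis=2)
    out = (1 - alpha) * base + alpha * colored
    arr8 = np.round(np.clip(out, 0, 1) * 255).astype(np.uint8)
    output_path = Path(output_path)
    output_path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr8, mode="RGB").save(output_path)
    return output_path


def render_branch_overlays(images: list[np.ndarray], heatmaps: list[Heatmap],
                           output_stem, branch_sizes) -> list[Path]:
    """One overlay per branch, file names suffixed by the branch size."""
    stem = Path(output_stem)
    paths = []
    for img, hm, side in zip(images, heatmaps, branch_sizes):
        paths.append(render_overlay(img, hm, stem.with_name(f"{stem.name}_{side}.png")))
    return paths
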