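"""Seg-Grad-CAM: gradient-weighted class activation maps for pixel sets.

For a target class ``c`` and a set of output pixels (a distinct border, a
completed border, the background, a full structure...), the scalar target
is the sum of the pre-softmax class-``c`` scores over the set.  The map is

    L^c = ReLU( sum_f  w_f A^f ),   w_f = mean_ij d(target)/dA^f_ij,

with A^f the activations of a chosen (by default the last) convolutional
layer and the weights the global average pooling of the gradients.  The
map is non-negative and lives at feature-map resolution; an upsampled
copy at input resolution is kept for display.  Quantitative comparisons
always use the raw (unnormalized) maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import ndimage

from .borders import BorderSplit
from .models import ModelAdapter

logger = logging.getLogger("usborder")


class TargetError(ValueError):
    """Empty or out-of-grid pixel-set target."""


@dataclass
class CAMTarget:
    """A class id plus the boolean set of output pixels to explain."""

    class_id: int
    pixel_set: np.ndarray

    def __post_init__(self):
        self.pixel_set = np.asarray(self.pixel_set, dtype=bool)
        if not self.pixel_set.any():
            raise TargetError("CAM target pixel set is empty")


@dataclass
class CAMMap:
    """A localization map with the ingredients that produced it."""

    map: np.ndarray                 # (h, w) at feature resolution, >= 0
    weights: np.ndarray             # pooled gradient per feature map
    activations: np.ndarray         # (K, h, w) cached A^f
    layer_name: str
    target: CAMTarget
    upsampled: np.ndarray = None    # at input resolution

    def reconstruct(self) -> np.ndarray:
        """Recompute ReLU(sum_f w_f A^f) from the stored pieces (bitwise
        equal to ``map``)."""
        return np.maximum(np.tensordot(self.weights, self.activations, axes=1), 0.0)


def scalar_target(scores: np.ndarray, target: CAMTarget) -> float:
    """Sum of the class's pre-softmax scores over the target pixel set."""
    scores = np.asarray(scores)
    if target.pixel_set.shape != scores.shape[1:]:
        raise TargetError(
            f"pixel set {target.pixel_set.shape} does not match "
            f"score grid {scores.shape[1:]}")
    if not (0 <= target.class_id < scores.shape[0]):
        raise TargetError(f"class {target.class_id} outside score channels")
    return float(scores[target.class_id][target.pixel_set].sum())


def compute_cam(model: ModelAdapter, image, target: CAMTarget,
                layer: str = "features") -> CAMMap:
    """Seg-Grad-CAM map of ``target`` at a named layer.

    The gradient of the summed class score with respect to the layer's
    activations is pooled spatially (one weight per feature map), combined
    with the activations and rectified.
    """
    scores = model.forward(image)
    if target.pixel_set.shape != scores.shape[1:]:
        raise TargetError("target pixel set does not match the model output grid")
    acts = model.activations(layer)
    d_scores = np.zeros_like(scores)
    d_scores[target.class_id][target.pixel_set] = 1.0
    grads = model.grad_wrt(layer, d_scores)
    if grads.shape != acts.shape:
        raise ValueError("adapter returned gradients mismatching activations")
    weights = grads.mean(axis=tuple(range(1, grads.ndim)))  # global average pool
    cam = np.maximum(np.tensordot(weights, acts, axes=1), 0.0)
    zoom = [t / s for t, s in zip(scores.shape[1:], cam.shape)]
    upsampled = (cam if all(z == 1 for z in zoom)
                 else ndimage.zoom(cam, zoom, order=1))
    return CAMMap(cam, weights, acts, layer, target, upsampled)


def cam_for_split(model: ModelAdapter, image, split: BorderSplit,
                  layer: str = "features"):
    """CAM maps for the distinct and completed parts of one class's border.

    Returns ``(distinct_map, completed_map)``; an empty part yields
    ``None`` with a warning rather than an error.
    """
    out = []
    for name, mask in (("distinct", split.distinct), ("completed", split.completed)):
        if not mask.any():
            logger.warning("%s border empty for class %d; CAM skipped",
                           name, split.class_id)
            out.append(None)
            continue
        out.append(compute_cam(model, image,
                               CAMTarget(split.class_id, mask), layer))
    return tuple(out)


@dataclass
class PerturbationResult:
    similarity: float         # cosine similarity of raw CAM maps
    baseline_region_mean: float
    perturbed_region_mean: float


def _perturb(data: np.ndarray, perturbation: str, params: dict, rng):
    out = data.astype(np.float64).copy()
    if perturbation == "zero_patch":
        sl = tuple(slice(a, b) for a, b in params["patch"])
        for (a, b), n in zip(params["patch"], data.shape):
            if not (0 <= a <= b <= n):
                raise ValueError(f"patch {params['patch']} outside grid {data.shape}")
        out[sl] = 0.0
        region = np.zeros(data.shape, bool)
        region[sl] = True
    elif perturbation == "gaussian_noise":
        sd = float(params.get("sd", 0.0))
        if sd < 0:
            raise ValueError("noise sd must be >= 0")
        out += rng.normal(0, sd, data.shape)
        region = np.ones(data.shape, bool)
    elif perturbation == "contrast_scale":
        factor = float(params.get("factor", 1.0))
        if factor <= 0:
            raise ValueError("contrast factor must be > 0")
        out = (out - out.mean()) * factor + out.mean()
        region = np.ones(data.shape, bool)
    else:
        raise ValueError(f"unknown perturbation {perturbation!r}")
    return out, region


def perturb_and_compare(model: ModelAdapter, image, target: CAMTarget,
                        layer: str = "features",
                        perturbation: str = "zero_patch",
                        params: dict = None, seed: int = 0) -> PerturbationResult:
    """Robustness probe: CAM similarity before/after an input perturbation.

    Perturbations: ``zero_patch`` (params["patch"] = per-axis (start, stop)
    index pairs), ``gaussian_noise`` (params["sd"]), ``contrast_scale``
    (params["factor"]).  Returns the cosine similarity of the two raw maps
    and the mean CAM value inside the perturbed region (at input
    resolution) for baseline and perturbed images.
    """
    params = params or {}
    rng = np.random.default_rng(seed)
    data = np.asarray(getattr(image, "data", image), dtype=np.float64)
    base = compute_cam(model, data, target, layer)
    pert_data, region = _perturb(data, perturbation, params, rng)
    pert = compute_cam(model, pert_data, target, layer)
    a, b = base.map.ravel(), pert.map.ravel()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 and nb == 0:
        sim = 1.0
    elif na == 0 or nb == 0:
        sim = 0.0
    else:
        sim = float(a @ b / (na * nb))
    return PerturbationResult(
        similarity=sim,
        baseline_region_mean=float(base.upsampled[region].mean()),
        perturbed_region_mean=float(pert.upsampled[region].mean()),
    )


def render_overlay(image, cam: CAMMap, out, contour_mask: np.ndarray = None,
                   cmap: str = "jet", alpha: float = 0.45):
    """Write a heatmap-over-grayscale figure (PNG).

    2D inputs give one panel; 3D inputs a mid-slice triplanar figure.  The
    heatmap is normalized by its maximum for display only.
    """
    data = np.asarray(getattr(image, "data", image), dtype=np.float64)
    heat = cam.upsampled if cam.upsampled is not None else cam.map
    hmax = heat.max()
    heat_disp = heat / hmax if hmax > 0 else heat

    def _panel(ax, img2d, heat2d, cont2d):
        ax.imshow(img2d, cmap="gray", interpolation="nearest")
        if heat2d.max() > 0:
            ax.imshow(heat2d, cmap=cmap, alpha=alpha * (heat2d > 0),
                      interpolation="bilinear", vmin=0, vmax=1)
        if cont2d is not None and cont2d.any():
            ax.contour(cont2d.astype(float), levels=[0.5], colors="white",
                       linewidths=0.8)
        ax.set_axis_off()

    if data.ndim == 2:
        fig, ax = plt.subplots(figsize=(4, 4))
        _panel(ax, data, heat_disp, contour_mask)
    else:
        mids = [s // 2 for s in data.shape]
        fig, axes = plt.subplots(1, 3, figsize=(12, 4))
        for axis, ax in enumerate(axes):
            sl = [slice(None)] * 3
            sl[axis] = mids[axis]
            cont = None if contour_mask is None else contour_mask[tuple(sl)]
            _panel(ax, data[tuple(sl)], heat_disp[tuple(sl)], cont)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
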