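"""Ultrasound-like phantoms with known distinct/completed border structure.

A phantom is a set of smooth soft-tissue blobs on a background, rendered
with the statistical features the border split assumes: bright interface
bands whose reflectivity decays exponentially with depth, multiplicative
log-normal speckle, and engineered *dropout* segments where the interface
is invisible and the annotator would have to complete the border.  The
generator returns the designed distinct/completed masks, so the whole
evaluation chain can be tested against a known ground truth.

Axis convention: the first spatial axis is depth (the probe sits at
index 0), so ``deep_sectors`` dropout removes interface signal from the
deepest border voxels, where real ultrasound signal is weakest.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .borders import extract_border
from .io import ImageVolume, LabelVolume
from .models import toy_model_fixture, train_small_unet  # noqa: F401  (fixture surface)

logger = logging.getLogger("usborder")


@dataclass
class PhantomSpec:
    """Knobs of the phantom generator; identical spec+seed => identical case.

    ``dropout_fraction`` is the designed fraction of each structure's
    border rendered without interface signal; ``attenuation_mu`` is the
    exponential decay of interface brightness per mm of depth.
    """

    shape: tuple = (96, 96)
    spacing: tuple = None
    n_classes: int = 4                  # background + 3 structures
    interface_brightness: float = 1.2
    attenuation_mu: float = 0.02        # per mm of depth
    speckle_sd: float = 0.10            # log-normal sigma
    dropout_fraction: float = 0.4
    dropout_geometry: str = "deep_sectors"
    tissue_means: tuple = None
    band_width: float = 3.2             # interface band reach, voxels
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if any(s <= 0 for s in self.shape):
            raise ValueError("shape must be positive")
        if self.spacing is None:
            self.spacing = (0.277,) * len(self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if not 0 <= self.dropout_fraction <= 1:
            raise ValueError("dropout_fraction must lie in [0, 1]")
        if self.attenuation_mu < 0:
            raise ValueError("attenuation_mu must be >= 0")
        if self.dropout_geometry not in ("deep_sectors", "random_arcs"):
            raise ValueError(f"unknown dropout_geometry {self.dropout_geometry!r}")
        if self.tissue_means is None:
            n_struct = self.n_classes - 1
            self.tissue_means = (0.35,) + tuple(
                0.45 + 0.10 * i for i in range(n_struct))
        self.tissue_means = tuple(float(m) for m in self.tissue_means)


@dataclass
class PhantomCase:
    """A generated phantom plus its designed border decomposition."""

    image: ImageVolume
    labels: LabelVolume
    designed_distinct: np.ndarray
    designed_completed: np.ndarray
    spec: PhantomSpec = None

    @property
    def border(self) -> np.ndarray:
        return self.designed_distinct | self.designed_completed


def _blob_labels(spec: PhantomSpec, rng) -> np.ndarray:
    """Smooth non-degenerate blobs: thresholded perturbed distance fields."""
    ndim = len(spec.shape)
    labels = np.zeros(spec.shape, dtype=np.int64)
    n_struct = spec.n_classes - 1
    coords = np.indices(spec.shape).astype(np.float64)
    extent = np.asarray(spec.shape, dtype=np.float64)
    # fixed anchor layout: structures spread over the cross-section
    if ndim == 2:
        anchors = [(0.34, 0.28), (0.38, 0.72), (0.68, 0.50),
                   (0.25, 0.50), (0.70, 0.20), (0.70, 0.80)]
    else:
        anchors = [(0.35, 0.32, 0.32), (0.38, 0.68, 0.68), (0.66, 0.50, 0.40),
                   (0.30, 0.55, 0.60), (0.68, 0.30, 0.65)]
    base_r = 0.17 * float(extent.min())
    for c in range(1, n_struct + 1):
        anchor = np.asarray(anchors[(c - 1) % len(anchors)]) * extent
        center = anchor + rng.uniform(-0.03, 0.03, ndim) * extent
        radius = base_r * rng.uniform(0.85, 1.15)
        d = np.sqrt(((coords - center.reshape(-1, *[1] * ndim)) ** 2).sum(0))
        bump = ndimage.gaussian_filter(rng.normal(0, 1, spec.shape),
                                       sigma=max(2.0, min(spec.shape) / 10))
        bmax = np.abs(bump).max()
        if bmax > 0:
            bump = bump / bmax * 0.22 * radius
        labels[d < radius + bump] = c
    return labels


def _select_dropout(border: np.ndarray, fraction: float, geometry: str,
                    center, rng) -> np.ndarray:
    """Choose an exact-count subset of one class's border as dropout."""
    idx = np.argwhere(border)
    n = len(idx)
    k = int(round(fraction * n))
    chosen = np.zeros(border.shape, bool)
    if k == 0:
        return chosen
    if geometry == "deep_sectors":
        # deepest border voxels first (axis 0 = depth), stable tie-break
        order = np.lexsort(tuple(idx[:, i] for i in range(idx.shape[1] - 1, 0, -1))
                           + (idx[:, 0],))[::-1]
        pick = idx[order[:k]]
    else:  # random_arcs: a contiguous angular window of exact size
        rel = idx[:, -2:] - np.asarray(center[-2:])
        ang = np.arctan2(rel[:, 0], rel[:, 1])
        order = np.argsort(ang, kind="stable")
        start = int(rng.integers(0, n))
        pick = idx[order[(start + np.arange(k)) % n]]
    chosen[tuple(pick.T)] = True
    return chosen


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Render one phantom and its designed distinct/completed masks.

    The label geometry is drawn first; each structure's inner border is
    split into a designed-completed subset (exact ``dropout_fraction`` of
    its voxel count) and the designed-distinct remainder.  Distinct
    segments receive a bright band just outside the structure with
    brightness ``interface_brightness * exp(-attenuation_mu * depth_mm)``;
    dropout segments receive no band and the underlying tissue step is
    locally blended away, making the interface invisible there.
    """
    rng = np.random.default_rng(spec.seed)
    lab = _blob_labels(spec, rng)
    labels = LabelVolume(lab, spec.spacing)
    ndim = lab.ndim

    distinct_all = np.zeros(spec.shape, bool)
    completed_all = np.zeros(spec.shape, bool)
    per_class = []
    for c in labels.classes():
        mask = lab == c
        border = extract_border(labels, c)
        center = np.argwhere(mask).mean(axis=0)
        completed = _select_dropout(border, spec.dropout_fraction,
                                    spec.dropout_geometry, center, rng)
        distinct = border & ~completed
        completed_all |= completed
        distinct_all |= distinct
        per_class.append((mask, distinct))

    band_strength = np.zeros(spec.shape, dtype=np.float64)
    depth_mm = np.indices(spec.shape)[0] * spec.spacing[0]
    atten = np.exp(-spec.attenuation_mu * depth_mm)
    if completed_all.any():
        dist_completed = ndimage.distance_transform_edt(~completed_all)
    else:
        dist_completed = np.full(spec.shape, np.inf)
    for mask, distinct in per_class:
        if distinct.any():
            # bright band strictly outside the structure: the border voxel
            # then sits on the maximal-slope flank of a smoothed step
            # rather than on a ridge crest where the gradient vanishes.
            # Each outside voxel takes the type of its nearest border voxel,
            # so the band reaches distinct segments' ends but never shadows
            # a dropout segment.
            border = distinct | (mask & completed_all)
            dist, nearest = ndimage.distance_transform_edt(
                ~border, return_indices=True)
            nearest_is_distinct = distinct[tuple(nearest)]
            band = ((dist <= spec.band_width) & ~mask & nearest_is_distinct
                    & (dist_completed > 2.0))
            band_strength[band] = np.maximum(
                band_strength[band], spec.interface_brightness)

    if not distinct_all.any() and spec.dropout_fraction < 1:
        logger.warning("phantom has no designed distinct border voxels")

    means = np.asarray(spec.tissue_means)[lab]
    # blend the tissue step away around dropout segments so the interface
    # is genuinely invisible there
    if completed_all.any():
        soft = ndimage.gaussian_filter(means, sigma=8.0)
        w = np.clip(1.0 - dist_completed / 9.0, 0.0, 1.0)
        means = w * soft + (1.0 - w) * means
    img = means + band_strength * atten
    img = ndimage.gaussian_filter(img, sigma=0.6)  # mild system PSF
    if spec.speckle_sd > 0:
        img = img * np.exp(rng.normal(0.0, spec.speckle_sd, spec.shape))
    image = ImageVolume(img.astype(np.float64), spec.spacing)
    return PhantomCase(image, labels, distinct_all, completed_all, spec)


def simulate_prediction(labels: LabelVolume, error_model: str = "dilate",
                        magnitude: float = 0, seed: int = 0) -> LabelVolume:
    """Degrade a label map to emulate an imperfect prediction.

    ``dilate`` grows every structure into the background by ``magnitude``
    voxels; ``erode`` shrinks it; ``elastic_jitter`` warps the whole map
    with a smooth random displacement field of peak ``magnitude`` voxels.
    Magnitude 0 returns an identical copy.
    """
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    lab = labels.data.copy()
    if magnitude == 0:
        return LabelVolume(lab, labels.spacing, labels.origin,
                           dict(labels.class_names))
    m = int(round(magnitude))
    if error_model == "dilate":
        for c in labels.classes():
            grown = ndimage.binary_dilation(labels.data == c, iterations=m)
            lab[grown & (labels.data == 0)] = c
    elif error_model == "erode":
        for c in labels.classes():
            mask = labels.data == c
            kept = ndimage.binary_erosion(mask, iterations=m, border_value=1)
            lab[mask & ~kept] = 0
    elif error_model == "elastic_jitter":
        rng = np.random.default_rng(seed)
        coords = np.indices(lab.shape).astype(np.float64)
        for ax in range(lab.ndim):
            disp = ndimage.gaussian_filter(rng.normal(0, 1, lab.shape),
                                           sigma=max(4.0, min(lab.shape) / 8))
            dmax = np.abs(disp).max()
            if dmax > 0:
                disp = disp / dmax * magnitude
            coords[ax] += disp
        lab = ndimage.map_coordinates(labels.data, coords, order=0,
                                      mode="nearest")
    else:
        raise ValueError(f"unknown error model {error_model!r}")
    return LabelVolume(lab, labels.spacing, labels.origin,
                       dict(labels.class_names))


def phantom_dataset(n: int, spec: PhantomSpec = None, seed: int = 0):
    """Generate ``n`` phantoms with independent geometry (seeded off ``seed``)."""
    if spec is None:
        spec = PhantomSpec()
    base = asdict(spec)
    out = []
    for i in range(n):
        base["seed"] = (seed * 100003 + i) % (2 ** 31)
        out.append(generate_phantom(PhantomSpec(**base)))
    return out
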