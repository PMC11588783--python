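"""Border extraction and the distinct/completed split.

An annotated border voxel is *distinct* where the image itself shows edge
evidence (element-wise product of the border mask with the binary edge
map) and *completed* where the annotator interpolated from anatomical
knowledge.  The two parts always partition the border exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .edges import EdgeMap, check_same_grid
from .io import LabelVolume

logger = logging.getLogger("usborder")


@dataclass
class BorderSplit:
    """Per-class border masks: ``distinct`` and ``completed`` partition ``border``."""

    class_id: int
    border: np.ndarray
    distinct: np.ndarray
    completed: np.ndarray
    tolerance_radius: int = 0

    def __post_init__(self):
        assert not np.any(self.distinct & self.completed)
        assert np.array_equal(self.distinct | self.completed, self.border)


def extract_border(labels: LabelVolume, class_id: int) -> np.ndarray:
    """Inner morphological boundary of one class.

    A voxel belongs to the border if it carries ``class_id`` and has at
    least one face-adjacent neighbour of a different class or lies on the
    grid edge (field-of-view truncation behaves like an interface).
    Face connectivity: 4 neighbours in 2D, 6 in 3D.
    """
    mask = labels.data == class_id
    if not mask.any():
        logger.warning("class %d absent from label map; empty border", class_id)
        return np.zeros(labels.shape, bool)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    # border_value=0 marks grid-edge voxels of the class as border
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~interior


def split_border(border: np.ndarray, edges: EdgeMap,
                 tolerance_radius: int = 0) -> BorderSplit:
    """Split a border mask into distinct and completed parts.

    ``tolerance_radius = 0`` is the strict element-wise (Hadamard) product
    of the border with the edge mask; a positive radius first dilates the
    edge mask by that many voxels (face connectivity) to absorb the
    half-voxel offset between a gradient ridge and the annotation.
    """
    check_same_grid(border, edges.mask)
    if tolerance_radius < 0:
        raise ValueError("tolerance_radius must be >= 0")
    evidence = edges.mask
    if tolerance_radius > 0:
        structure = ndimage.generate_binary_structure(border.ndim, 1)
        evidence = ndimage.binary_dilation(
            evidence, structure=structure, iterations=int(tolerance_radius))
    distinct = border & evidence
    completed = border & ~distinct
    return BorderSplit(-1, border, distinct, completed, int(tolerance_radius))


def split_all_classes(labels: LabelVolume, edges: EdgeMap,
                      tolerance_radius: int = 0) -> list:
    """One :class:`BorderSplit` per nonzero class, background excluded."""
    check_same_grid(labels.data, edges.mask)
    classes = labels.classes()
    if not classes:
        logger.warning("label map contains only background; no borders to split")
        return []
    out = []
    for c in classes:
        border = extract_border(labels, c)
        split = split_border(border, edges, tolerance_radius)
        split.class_id = c
        out.append(split)
    return out
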