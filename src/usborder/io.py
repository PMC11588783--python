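"""Volume and label-map I/O with consistent grid metadata.

All arrays use (z, y, x) index order for 3D and (y, x) for 2D; ``spacing``
and ``origin`` follow the same axis order, in millimetres.  Physical
position of a voxel is ``origin + index * spacing`` (axis-aligned grids;
direction matrices are not honoured beyond a warning).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import SimpleITK as sitk

logger = logging.getLogger("usborder")

_ITK_EXTS = (".nii", ".nii.gz", ".mhd", ".mha")
_PNG_EXTS = (".png",)


class FormatError(ValueError):
    """Raised for unsupported or malformed on-disk volumes."""


class GridError(ValueError):
    """Raised when two grids that must share a shape/spacing do not."""


@dataclass
class ImageVolume:
    """A scalar intensity grid with physical spacing.

    Parameters
    ----------
    data : ndarray
        2D ``(y, x)`` or 3D ``(z, y, x)`` array of intensities.
    spacing : tuple of float
        Per-axis voxel size in mm, same axis order as ``data``.
    origin : tuple of float
        Physical coordinates of voxel ``(0, ..., 0)``.
    """

    data: np.ndarray
    spacing: tuple = None
    origin: tuple = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise GridError(f"volume must be 2D or 3D, got ndim={self.data.ndim}")
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise GridError("spacing length must match data dimensionality")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.origin is None:
            self.origin = (0.0,) * self.data.ndim
        self.origin = tuple(float(o) for o in self.origin)
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("image data must be finite everywhere")

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim


@dataclass
class LabelVolume:
    """An integer class map on the same grid contract as :class:`ImageVolume`.

    Class 0 is reserved for background.
    """

    data: np.ndarray
    spacing: tuple = None
    origin: tuple = None
    class_names: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim not in (2, 3):
            raise GridError(f"label map must be 2D or 3D, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            as_int = np.rint(self.data).astype(np.int64)
            if not np.array_equal(as_int, self.data):
                bad = self.data[as_int != self.data].flat[0]
                raise FormatError(f"label values must be integers; found {bad!r}")
            self.data = as_int
        if self.data.min() < 0:
            raise ValueError("label values must be non-negative")
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim:
            raise GridError("spacing length must match data dimensionality")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.origin is None:
            self.origin = (0.0,) * self.data.ndim
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def classes(self):
        """Sorted nonzero class ids present in the map."""
        ids = np.unique(self.data)
        return [int(c) for c in ids if c != 0]


def check_paired(image: ImageVolume, labels: LabelVolume):
    """Raise :class:`GridError` unless image and labels share grid and spacing."""
    if image.shape != labels.shape:
        raise GridError(f"shape mismatch: image {image.shape} vs labels {labels.shape}")
    if not np.allclose(image.spacing, labels.spacing):
        raise GridError(
            f"spacing mismatch: image {image.spacing} vs labels {labels.spacing}"
        )


def _ext_of(path: str) -> str:
    p = str(path).lower()
    if p.endswith(".nii.gz"):
        return ".nii.gz"
    return os.path.splitext(p)[1]


def _read_itk(path: str):
    img = sitk.ReadImage(str(path))
    direction = np.asarray(img.GetDirection()).reshape(img.GetDimension(), -1)
    if not np.allclose(direction, np.eye(img.GetDimension()), atol=1e-6):
        logger.warning(
            "%s has a non-identity direction matrix; axes are treated as aligned",
            path,
        )
    # GetArrayFromImage returns (z, y, x); ITK spacing/origin are (x, y, z).
    data = sitk.GetArrayFromImage(img)
    spacing = tuple(reversed(img.GetSpacing()))
    origin = tuple(reversed(img.GetOrigin()))
    return data, spacing, origin


def read_volume(path, kind: str = "image"):
    """Read a volume from NIfTI, MetaImage or PNG.

    Parameters
    ----------
    path : str or Path
        File to read; ``.nii``/``.nii.gz``/``.mhd``/``.mha``/``.png``.
    kind : {"image", "label"}
        ``"label"`` validates integer content and returns a
        :class:`LabelVolume`.

    Returns
    -------
    ImageVolume or LabelVolume
    """
    if kind not in ("image", "label"):
        raise ValueError(f"kind must be 'image' or 'label', got {kind!r}")
    ext = _ext_of(path)
    if ext in _ITK_EXTS:
        data, spacing, origin = _read_itk(path)
    elif ext in _PNG_EXTS:
        data = np.asarray(iio.imread(path))
        if data.ndim == 3:  # collapse RGB(A) to luminance for scalar grids
            data = data[..., :3].mean(axis=-1)
        spacing = (1.0, 1.0)
        origin = (0.0, 0.0)
        logger.warning("PNG %s carries no spacing metadata; assuming 1x1 mm", path)
    else:
        raise FormatError(f"unsupported volume extension: {path}")
    if kind == "label":
        return LabelVolume(data, spacing, origin)
    return ImageVolume(np.asarray(data, dtype=np.float32), spacing, origin)


def write_volume(vol, path):
    """Write a volume; format chosen by extension.

    Images are stored as float32, labels and boolean masks as unsigned
    integers.  Round-trips through :func:`read_volume` are bitwise stable
    for integer data and float32-exact for images.
    """
    ext = _ext_of(path)
    data = vol.data
    if ext in _ITK_EXTS:
        if isinstance(vol, LabelVolume) or data.dtype == bool or np.issubdtype(
            data.dtype, np.integer
        ):
            out = data.astype(np.uint8 if data.max(initial=0) < 256 else np.uint16)
        else:
            out = data.astype(np.float32)
        img = sitk.GetImageFromArray(out)
        img.SetSpacing(tuple(reversed(vol.spacing)))
        img.SetOrigin(tuple(reversed(vol.origin)))
        sitk.WriteImage(img, str(path))
    elif ext in _PNG_EXTS:
        if data.ndim != 2:
            raise FormatError("PNG supports 2D grids only")
        if data.dtype == bool or np.issubdtype(data.dtype, np.integer):
            out = data.astype(np.uint8)
        else:
            lo, hi = float(data.min()), float(data.max())
            scale = 255.0 / (hi - lo) if hi > lo else 0.0
            out = ((data - lo) * scale).astype(np.uint8)
        iio.imwrite(path, out)
    else:
        raise FormatError(f"unsupported volume extension: {path}")
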