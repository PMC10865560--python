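"""Core volumetric containers and NIfTI I/O.

Conventions used throughout the package
---------------------------------------
* Grid axis order is (right–left, anterior–posterior, foot–head); the
  left–right axis is the first grid axis.
* Voxel indices are 0-based; the affine maps voxel indices to world
  coordinates in mm.  In template space the midline is the world x = 0
  plane (x is the first world coordinate).
* Label codes: 0 background, 1 sinus lumen, 2 parasagittal dural space
  (PSD), 3 arachnoid granulation (AG).
* Patches are 96 x 64 x 64 voxels (anterior–posterior x foot–head x
  right–left), i.e. shape ``(64, 96, 64)`` in grid axis order.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np

__all__ = [
    "LABEL_CODES",
    "PATCH_SHAPE",
    "Volume3D",
    "LabelMap",
    "Patch",
    "read_volume",
    "write_volume",
    "read_labels",
    "write_labels",
    "voxel_volume",
]

#: integer code -> structure name
LABEL_CODES = {0: "background", 1: "sinus_lumen", 2: "psd", 3: "ag"}

#: fixed patch shape in grid axis order (RL, AP, FH); the anatomical
#: extent is 96 voxels anterior–posterior and 64 along the other axes.
PATCH_SHAPE = (64, 96, 64)


class DimensionalityError(ValueError):
    """Raised when an on-disk image is not a 3-D scalar volume."""


class LabelCodeError(ValueError):
    """Raised when a label map contains a code outside {0, 1, 2, 3}."""


def _validate_grid(data: np.ndarray, spacing, affine: np.ndarray) -> None:
    if data.ndim != 3:
        raise DimensionalityError(
            f"expected a 3-D grid, got {data.ndim} axes (shape {data.shape})"
        )
    if min(data.shape) < 1:
        raise ValueError("every grid axis must have length >= 1")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ValueError(f"spacing must be three positive values, got {spacing}")
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine must be an invertible 4x4 matrix")


@dataclass
class Volume3D:
    """A 3-D scalar intensity grid with voxel spacing and affine."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    space_tag: str = "native"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        self.spacing = tuple(float(s) for s in np.asarray(self.spacing).ravel())
        _validate_grid(self.data, self.spacing, self.affine)
        if self.space_tag not in ("native", "template"):
            raise ValueError(f"space_tag must be 'native' or 'template', got {self.space_tag!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinate of every voxel, one array per world axis."""
        idx = np.indices(self.data.shape, dtype=float)
        A, t = self.affine[:3, :3], self.affine[:3, 3]
        coords = np.einsum("ij,j...->i...", A, idx) + t[:, None, None, None]
        return coords[0], coords[1], coords[2]

    def with_data(self, data: np.ndarray, space_tag: Optional[str] = None) -> "Volume3D":
        return Volume3D(data, self.spacing, self.affine.copy(),
                        space_tag or self.space_tag)


@dataclass
class LabelMap:
    """Integer label grid sharing the lattice of a companion :class:`Volume3D`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    space_tag: str = "native"
    codes: dict = field(default_factory=lambda: dict(LABEL_CODES))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise LabelCodeError("label map contains non-integer voxel values")
            self.data = rounded.astype(np.int16)
        self.affine = np.asarray(self.affine, dtype=float)
        self.spacing = tuple(float(s) for s in np.asarray(self.spacing).ravel())
        _validate_grid(self.data, self.spacing, self.affine)
        bad = np.setdiff1d(np.unique(self.data), list(self.codes))
        if bad.size:
            raise LabelCodeError(
                f"label map contains out-of-range code(s) {bad.tolist()}; "
                f"allowed codes are {sorted(self.codes)}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_coords(self):
        return Volume3D.world_coords(self)  # same lattice bookkeeping

    def with_data(self, data: np.ndarray, space_tag: Optional[str] = None) -> "LabelMap":
        return LabelMap(data, self.spacing, self.affine.copy(),
                        space_tag or self.space_tag)

    def same_grid(self, other) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.affine, other.affine)
                and np.allclose(self.spacing, other.spacing))


@dataclass
class Patch:
    """Fixed-shape patch extracted from a volume.

    ``data`` is either ``PATCH_SHAPE`` or ``PATCH_SHAPE + (channels,)``;
    ``origin`` is the voxel index of the patch corner in the source volume
    (may be negative near boundaries); ``pad_mask`` flags voxels that fall
    outside the source volume and were zero-padded.
    """

    data: np.ndarray
    origin: tuple[int, int, int]
    pad_mask: np.ndarray

    def __post_init__(self) -> None:
        spatial = self.data.shape[:3]
        if tuple(spatial) != PATCH_SHAPE:
            raise ValueError(f"patch shape must be {PATCH_SHAPE}, got {spatial}")
        if self.pad_mask.shape != PATCH_SHAPE:
            raise ValueError("pad_mask must match the patch spatial shape")


def read_volume(path) -> Volume3D:
    """Read a NIfTI-1 scalar volume; spacing/affine taken from the header."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path.name}: expected a 3-D image, got shape {data.shape}"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(data, spacing, np.asarray(img.affine))


def write_volume(vol: Volume3D, path) -> None:
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def read_labels(path) -> LabelMap:
    """Read a NIfTI-1 label map; codes are validated against {0,1,2,3}."""
    vol = read_volume(path)
    return LabelMap(vol.data, vol.spacing, vol.affine, vol.space_tag)


def write_labels(labels: LabelMap, path) -> None:
    img = nib.Nifti1Image(np.asarray(labels.data, dtype=np.int16), labels.affine)
    img.header.set_zooms(labels.spacing)
    nib.save(img, str(path))


def voxel_volume(v) -> float:
    """Volume of one voxel in mm^3 (product of the spacing components)."""
    return float(np.prod(v.spacing))
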