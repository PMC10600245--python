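"""Minimal 3D image and segmentation containers.

Arrays are stored in ``(x, y, z)`` index order with physical voxel spacing
``spacing_mm = (sx, sy, sz)`` so that an *axial slice* is a fixed ``z``
index, matching the slice-by-slice contouring convention of clinical
segmentations.  NIfTI I/O goes through nibabel; only spacing (not full
affine orientation) is tracked because every operation in this package is
spacing-aware but orientation-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "SegmentationMask", "load_volume", "load_mask"]


@dataclass
class ImageVolume:
    """A 3D scalar image with physical voxel spacing in millimetres."""

    array: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=np.float64)
        if self.array.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.array.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_mm}")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.array.shape

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.array.copy(), self.spacing_mm, self.origin_mm)

    def same_grid(self, other: "ImageVolume | SegmentationMask") -> bool:
        return (
            self.array.shape == other.array.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(self.array.astype(np.float32), affine), str(path))


@dataclass
class SegmentationMask:
    """A binary ROI mask aligned to an :class:`ImageVolume` grid."""

    array: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array) > 0.5
        if self.array.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.array.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing_mm}")
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.array.shape

    @property
    def voxel_count(self) -> int:
        return int(self.array.sum())

    def is_empty(self) -> bool:
        return not self.array.any()

    def copy(self) -> "SegmentationMask":
        return SegmentationMask(self.array.copy(), self.spacing_mm, self.origin_mm)

    def same_grid(self, other: "ImageVolume | SegmentationMask") -> bool:
        return (
            self.array.shape == other.array.shape
            and np.allclose(self.spacing_mm, other.spacing_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def bounding_box(self) -> tuple[slice, slice, slice]:
        """Tight bounding box of the foreground as slices per axis."""
        if self.is_empty():
            raise ValueError("bounding box of an empty mask is undefined")
        idx = np.nonzero(self.array)
        return tuple(slice(int(a.min()), int(a.max()) + 1) for a in idx)

    def bounding_box_center_mm(self) -> np.ndarray:
        """Physical coordinates (mm) of the bounding-box centre."""
        box = self.bounding_box()
        centre_vox = np.array([(s.start + s.stop - 1) / 2.0 for s in box])
        return centre_vox * np.asarray(self.spacing_mm) + np.asarray(self.origin_mm)

    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag(list(self.spacing_mm) + [1.0])
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(self.array.astype(np.uint8), affine), str(path))


def _spacing_from_affine(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def load_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return ImageVolume(np.asarray(img.get_fdata(), dtype=np.float64),
                       _spacing_from_affine(img), origin)


def load_mask(path: str | Path) -> SegmentationMask:
    img = nib.load(str(path))
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return SegmentationMask(np.asarray(img.get_fdata()) > 0.5,
                            _spacing_from_affine(img), origin)
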