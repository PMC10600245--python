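"""Image preprocessing ahead of feature extraction.

The chain is: isotropic resampling (cubic spline for the image, linear +
0.5 threshold for the mask, grid origins aligned), then a filter bank
(identity, 3D Laplacian-of-Gaussian at several physical scales, and a
single-level undecimated coiflet-1 wavelet decomposition), and finally a
fixed-bin-number gray-level discretization computed within the ROI of
each filtered image separately.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .image import ImageVolume, SegmentationMask

__all__ = [
    "PreprocessConfig",
    "resample_isotropic",
    "discretize",
    "log_filter",
    "wavelet_bank",
    "filtered_images",
]

WAVELET_LABELS = ("LLL", "HLL", "LHL", "LLH", "LHH", "HLH", "HHL", "HHH")


@dataclass
class PreprocessConfig:
    """Preprocessing settings; defaults give the standard extraction protocol."""

    target_spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bin_count: int = 32
    log_kernels_mm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 5.0)
    wavelet_name: str = "coif1"
    wavelet_level: int = 1
    use_wavelet: bool = True

    def __post_init__(self) -> None:
        if self.bin_count < 2:
            raise ValueError("bin_count must be >= 2")
        if any(k <= 0 for k in self.log_kernels_mm):
            raise ValueError("LoG kernel sizes must be positive")
        if any(s <= 0 for s in self.target_spacing_mm):
            raise ValueError("target spacing must be positive")

    @property
    def image_labels(self) -> list[str]:
        labels = ["original"]
        labels += [f"log-sigma-{k:g}mm" for k in self.log_kernels_mm]
        if self.use_wavelet:
            labels += [f"wavelet-{w}" for w in WAVELET_LABELS]
        return labels


def resample_isotropic(
    image: ImageVolume, mask: SegmentationMask, config: PreprocessConfig
) -> tuple[ImageVolume, SegmentationMask]:
    """Resample image and mask onto the target isotropic grid.

    Origins are aligned: output voxel ``j`` sits at physical position
    ``j * target_spacing`` in the input frame.  Image values are
    interpolated with a cubic spline, the mask linearly with a 0.5
    partial-volume threshold.
    """
    if not image.same_grid(mask):
        raise ValueError("image and mask grids are not aligned")
    src = np.asarray(image.spacing_mm)
    dst = np.asarray(config.target_spacing_mm)
    if np.allclose(src, dst):
        return image.copy(), mask.copy()
    extent = (np.asarray(image.shape) - 1) * src
    out_shape = tuple(int(np.floor(e / d)) + 1 for e, d in zip(extent, dst))
    grid = np.mgrid[[slice(0, n) for n in out_shape]].astype(np.float64)
    coords = np.stack([grid[d] * dst[d] / src[d] for d in range(3)])
    # cubic spline with not-a-knot boundaries: no edge ringing, exact on ramps
    interp = RegularGridInterpolator(
        tuple(np.arange(n, dtype=np.float64) for n in image.shape),
        image.array, method="cubic", bounds_error=False, fill_value=0.0)
    img_out = interp(coords.reshape(3, -1).T).reshape(out_shape)
    msk_out = ndimage.map_coordinates(mask.array.astype(np.float64), coords,
                                      order=1, mode="constant", cval=0.0) >= 0.5
    if not msk_out.any():
        raise ValueError("resampling emptied the mask")
    spacing = tuple(float(d) for d in dst)
    return (ImageVolume(img_out, spacing, image.origin_mm),
            SegmentationMask(msk_out, spacing, mask.origin_mm))


def discretize(
    image: ImageVolume | np.ndarray, mask: SegmentationMask, bin_count: int
) -> np.ndarray:
    """Fixed-bin-number gray-level discretization within the ROI.

    ROI intensities are mapped to integer levels ``1..bin_count`` with a
    bin width of ``(max - min) / bin_count`` computed over ROI voxels;
    the maximum maps to the top bin.  Returns an integer array on the
    full grid with 0 outside the ROI.
    """
    arr = image.array if isinstance(image, ImageVolume) else np.asarray(image)
    if mask.is_empty():
        raise ValueError("cannot discretize an empty ROI")
    roi = arr[mask.array]
    lo, hi = float(roi.min()), float(roi.max())
    out = np.zeros(arr.shape, dtype=np.int64)
    if hi == lo:
        warnings.warn("constant ROI: all voxels assigned to bin 1")
        out[mask.array] = 1
        return out
    width = (hi - lo) / bin_count
    levels = np.floor((roi - lo) / width).astype(np.int64) + 1
    np.clip(levels, 1, bin_count, out=levels)
    out[mask.array] = levels
    return out


def log_filter(image: ImageVolume, kernel_mm: float) -> ImageVolume:
    """Scale-normalized 3D Laplacian-of-Gaussian response at a physical scale.

    Implemented as Gaussian smoothing (physical ``sigma = kernel_mm``)
    followed by the discrete Laplacian, scaled by ``sigma^2`` so
    responses at different scales are comparable.  The discrete
    Laplacian annihilates constants exactly.
    """
    if kernel_mm <= 0:
        raise ValueError("kernel_mm must be positive")
    sigma_vox = [kernel_mm / s for s in image.spacing_mm]
    smoothed = ndimage.gaussian_filter(image.array, sigma=sigma_vox, mode="nearest")
    resp = np.zeros_like(smoothed)
    for d, sp in enumerate(image.spacing_mm):
        resp += np.gradient(np.gradient(smoothed, sp, axis=d), sp, axis=d)
    return ImageVolume(kernel_mm**2 * resp, image.spacing_mm, image.origin_mm)


def _swt_filters(wavelet_name: str) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(wavelet_name)
    return np.asarray(w.dec_lo, dtype=np.float64), np.asarray(w.dec_hi, dtype=np.float64)


def _conv_along(arr: np.ndarray, kernel: np.ndarray, axis: int) -> np.ndarray:
    # periodic undecimated filtering along one axis
    return ndimage.convolve1d(arr, kernel, axis=axis, mode="wrap")


def wavelet_bank(image: ImageVolume, config: PreprocessConfig) -> dict[str, ImageVolume]:
    """Single-level undecimated 3D wavelet decomposition.

    Returns the eight high/low-pass combinations labelled ``LLL..HHH``
    (letter order = array axes x, y, z; L = low pass, H = high pass),
    each on the same grid as the input.  Implemented as separable
    periodic convolutions with the wavelet's decomposition filters,
    which keeps the outputs grid-aligned.
    """
    lo, hi = _swt_filters(config.wavelet_name)
    bands = {"L": lo, "H": hi}
    out: dict[str, ImageVolume] = {}
    for label in WAVELET_LABELS:
        vol = image.array
        for axis, letter in enumerate(label):
            vol = _conv_along(vol, bands[letter], axis)
        out[label] = ImageVolume(vol, image.spacing_mm, image.origin_mm)
    return out


def filtered_images(image: ImageVolume, config: PreprocessConfig) -> dict[str, ImageVolume]:
    """All filtered images keyed by label (original, LoG scales, wavelets)."""
    out = {"original": image}
    for k in config.log_kernels_mm:
        out[f"log-sigma-{k:g}mm"] = log_filter(image, k)
    if config.use_wavelet:
        for label, vol in wavelet_bank(image, config).items():
            out[f"wavelet-{label}"] = vol
    return out
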