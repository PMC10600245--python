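"""Pseudo test-retest generation by image perturbation.

A perturbation is a random combination of a small rigid transform
(in-plane rotation about the axial axis through the mask bounding-box
centre, plus a sub-voxel translation) and a *contour randomization* that
deforms the segmentation with a smooth random displacement field.  The
field construction keeps the through-slice (z) displacement constant
within each axial slice, emulating the uniform inter-slice variation of
slice-by-slice manual contouring, and normalizes each component to a
user-defined physical root-mean-square intensity before Gaussian
smoothing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import ImageVolume, SegmentationMask

__all__ = [
    "PerturbationSpace",
    "PerturbationSpec",
    "sample_spec",
    "build_displacement_field",
    "randomize_contour",
    "apply_rigid",
    "perturb_subject",
]


@dataclass
class PerturbationSpace:
    """The grid of admissible perturbation parameters.

    Default protocol: per-axis translations drawn from
    {0, 0.2, 0.4, 0.6, 0.8} pixels with random sign, rotations from
    {-5, 0, 5} degrees about the axial axis, and contour randomization
    with 10 mm smoothing sigma and 1 mm RMS intensity per dimension.
    """

    translation_magnitudes_px: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8)
    rotation_angles_deg: tuple[float, ...] = (-5.0, 0.0, 5.0)
    contour_sigma_mm: tuple[float, float, float] = (10.0, 10.0, 10.0)
    contour_intensity_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_perturbations: int = 40

    def __post_init__(self) -> None:
        if len(self.translation_magnitudes_px) == 0 or len(self.rotation_angles_deg) == 0:
            raise ValueError("translation and rotation grids must be non-empty")
        if any(s <= 0 for s in self.contour_sigma_mm):
            raise ValueError("contour sigma components must be positive")
        if any(i < 0 for i in self.contour_intensity_mm):
            raise ValueError("contour intensity components must be non-negative")
        if self.n_perturbations < 1:
            raise ValueError("n_perturbations must be >= 1")


@dataclass(frozen=True)
class PerturbationSpec:
    """One sampled perturbation: signed translation, rotation, contour seed."""

    translation_px: tuple[float, float, float]
    rotation_deg: float
    contour_seed: int

    def is_rigid_identity(self) -> bool:
        return self.rotation_deg == 0.0 and all(t == 0.0 for t in self.translation_px)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def sample_spec(space: PerturbationSpace, rng: np.random.Generator | int) -> PerturbationSpec:
    """Draw one random perturbation from the space.

    Each axis gets an independent uniform draw from the translation
    magnitude grid with an independent random sign; a single rotation
    angle is drawn uniformly from the angle grid; a fresh contour seed is
    drawn for the displacement field.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mags = rng.choice(np.asarray(space.translation_magnitudes_px, dtype=float), size=3)
    signs = rng.choice([-1.0, 1.0], size=3)
    angle = float(rng.choice(np.asarray(space.rotation_angles_deg, dtype=float)))
    seed = int(rng.integers(0, 2**31 - 1))
    return PerturbationSpec(tuple(float(m * s) for m, s in zip(mags, signs)), angle, seed)


def build_displacement_field(
    shape: tuple[int, int, int],
    spacing_mm: tuple[float, float, float],
    sigma_mm: tuple[float, float, float],
    intensity_mm: tuple[float, float, float],
    seed: int | np.random.Generator,
    smooth: bool = True,
) -> np.ndarray:
    """Random displacement field (mm) of shape ``(3,) + shape``.

    Construction order:

    1. i.i.d. uniform(-1, 1) per voxel for each of the three components;
    2. the z-component of every voxel in an axial slice is overwritten by
       one shared uniform(-1, 1) draw per slice;
    3. each component is divided by its root mean square over all voxels
       and multiplied by that component's ``intensity_mm``;
    4. each component is smoothed by a Gaussian with physical ``sigma_mm``
       (skipped when ``smooth=False``, exposing the normalized raw field).

    The slice-constancy of the z-component survives smoothing because the
    Gaussian weights are identical for all in-plane positions.
    """
    if len(shape) != 3 or shape[2] < 2:
        raise ValueError("displacement field requires a 3D grid with >= 2 slices")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    field = rng.uniform(-1.0, 1.0, size=(3,) + tuple(shape))
    # one shared z draw per axial slice
    z_per_slice = rng.uniform(-1.0, 1.0, size=shape[2])
    field[2] = np.broadcast_to(z_per_slice, shape).copy()
    for d in range(3):
        rms = np.sqrt(np.mean(field[d] ** 2))
        if rms == 0.0:
            raise ValueError(f"zero RMS on dimension {d}")
        field[d] *= intensity_mm[d] / rms
    sigma_vox = [s / p for s, p in zip(sigma_mm, spacing_mm)]
    for d in range(3):
        if intensity_mm[d] == 0.0:
            field[d] = 0.0
        elif smooth:
            field[d] = ndimage.gaussian_filter(field[d], sigma=sigma_vox, mode="nearest")
    return field


def randomize_contour(mask: SegmentationMask, field: np.ndarray) -> SegmentationMask:
    """Warp the mask by a displacement field (backward warping).

    The output voxel at index ``v`` samples the input mask at
    ``v + field(v)/spacing`` with linear interpolation, re-binarized at
    the 0.5 partial-volume threshold.
    """
    if field.shape != (3,) + mask.array.shape:
        raise ValueError("field grid does not match mask grid")
    if not field.any():
        return mask.copy()
    coords = np.mgrid[[slice(0, n) for n in mask.array.shape]].astype(np.float64)
    for d in range(3):
        coords[d] += field[d] / mask.spacing_mm[d]
    warped = ndimage.map_coordinates(mask.array.astype(np.float64), coords,
                                     order=1, mode="constant", cval=0.0)
    out = warped >= 0.5
    if not out.any():
        raise ValueError("contour randomization emptied the mask")
    return SegmentationMask(out, mask.spacing_mm, mask.origin_mm)


def _rigid_backward_coords(
    shape: tuple[int, int, int],
    spacing: np.ndarray,
    centre_mm: np.ndarray,
    rotation_deg: float,
    translation_mm: np.ndarray,
) -> np.ndarray:
    """Backward-warp voxel coordinates for rotation-then-translation.

    Forward map: y = R (x - c) + c + t, rotation about the z axis through
    physical centre c.  Backward: x = R^T (y - c - t) + c.
    """
    theta = np.deg2rad(rotation_deg)
    cos, sin = np.cos(theta), np.sin(theta)
    grid = np.mgrid[[slice(0, n) for n in shape]].astype(np.float64)
    phys = [grid[d] * spacing[d] for d in range(3)]
    u = phys[0] - centre_mm[0] - translation_mm[0]
    v = phys[1] - centre_mm[1] - translation_mm[1]
    w = phys[2] - centre_mm[2] - translation_mm[2]
    # R^T for rotation by theta in the x-y plane
    x = cos * u + sin * v + centre_mm[0]
    y = -sin * u + cos * v + centre_mm[1]
    z = w + centre_mm[2]
    return np.stack([x / spacing[0], y / spacing[1], z / spacing[2]])


def apply_rigid(
    image: ImageVolume, mask: SegmentationMask, spec: PerturbationSpec
) -> tuple[ImageVolume, SegmentationMask]:
    """Rotate about the axial axis through the mask bounding-box centre,
    then translate by ``spec.translation_px`` (fractional voxels).

    The image is resampled with cubic-spline interpolation, the mask with
    linear interpolation re-binarized at 0.5; out-of-field voxels take
    value 0.  An identity spec is a bit-exact no-op.
    """
    if not image.same_grid(mask):
        raise ValueError("image and mask grids are not aligned")
    if spec.is_rigid_identity():
        return image.copy(), mask.copy()
    spacing = np.asarray(image.spacing_mm)
    centre = mask.bounding_box_center_mm() - np.asarray(image.origin_mm)
    translation_mm = np.asarray(spec.translation_px) * spacing
    coords = _rigid_backward_coords(image.shape, spacing, centre,
                                    spec.rotation_deg, translation_mm)
    warped_img = ndimage.map_coordinates(image.array, coords, order=3,
                                         mode="constant", cval=0.0)
    warped_msk = ndimage.map_coordinates(mask.array.astype(np.float64), coords,
                                         order=1, mode="constant", cval=0.0) >= 0.5
    if not warped_msk.any():
        raise ValueError("rigid transform emptied the mask")
    return (
        ImageVolume(warped_img, image.spacing_mm, image.origin_mm),
        SegmentationMask(warped_msk, mask.spacing_mm, mask.origin_mm),
    )


def perturb_subject(
    image: ImageVolume,
    mask: SegmentationMask,
    space: PerturbationSpace,
    n: int | None = None,
    seed: int | np.random.Generator = 0,
) -> list[tuple[ImageVolume, SegmentationMask, PerturbationSpec]]:
    """Generate ``n`` independent perturbed copies of one subject.

    Each copy applies a freshly sampled rigid transform to image and
    mask, then contour-randomizes the rigidly transformed mask.  Returns
    the perturbed pairs together with the specs for exact replay.
    """
    if n is None:
        n = space.n_perturbations
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = []
    for _ in range(n):
        spec = sample_spec(space, rng)
        img_p, msk_p = apply_rigid(image, mask, spec)
        if any(i > 0 for i in space.contour_intensity_mm):
            field = build_displacement_field(
                msk_p.shape, msk_p.spacing_mm,
                space.contour_sigma_mm, space.contour_intensity_mm,
                spec.contour_seed,
            )
            msk_p = randomize_contour(msk_p, field)
        out.append((img_p, msk_p, spec))
    return out
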