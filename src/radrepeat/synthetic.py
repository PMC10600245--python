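"""Self-contained synthetic imaging cohorts.

Each subject carries one tumor-like blob — an ellipsoid with a smooth
random boundary deformation — filled with a band-limited random texture
on a noisy background.  A binary outcome is drawn from a logistic model
on two latent parameters (texture amplitude and boundary irregularity),
so a subset of extracted radiomic features is genuinely predictive.
Test-retest pairs re-noise the clean image, optionally shift it rigidly,
and re-draw the segmentation with an independent contour randomization
whose intensity exceeds the perturbation setting — emulating the larger
segmentation variation of true repeat scans.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from sklearn.model_selection import train_test_split

from .image import ImageVolume, SegmentationMask
from .perturbation import PerturbationSpec, apply_rigid, build_displacement_field, randomize_contour

__all__ = ["CohortConfig", "SyntheticCohort", "generate_cohort", "split_cohort"]


@dataclass
class CohortConfig:
    """Generation settings for a synthetic cohort.

    Defaults describe the standard study conditions used throughout the
    test suite: 60 subjects on a 32^3 grid at 1 mm isotropic spacing,
    tumors of 6-10 mm radius, 30% outcome prevalence, and retest
    segmentation variation tuned to a mean Dice near 0.55.
    """

    n_subjects: int = 60
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius_mm: tuple[float, float] = (6.0, 10.0)
    texture_contrast: float = 15.0
    noise_sd: float = 2.0
    outcome_prevalence: float = 0.3
    effect_size: float = 2.0
    retest_shift_mm: float = 1.0
    retest_contour_sigma_mm: float = 5.0
    retest_contour_intensity_mm: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if any(n < 8 for n in self.grid_shape):
            raise ValueError(f"degenerate grid {self.grid_shape}: every dimension must be >= 8 voxels")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing components must be positive")
        if not 0.0 < self.outcome_prevalence < 1.0:
            raise ValueError("outcome_prevalence must lie strictly inside (0, 1)")
        if self.retest_contour_sigma_mm <= 0:
            raise ValueError("retest_contour_sigma_mm must be positive")
        if self.retest_shift_mm < 0 or self.retest_contour_intensity_mm < 0:
            raise ValueError("retest perturbation magnitudes must be non-negative")


@dataclass
class SyntheticCohort:
    """A generated cohort: images, masks, retest pairs, outcomes, truth."""

    subject_ids: list[str]
    subjects: dict[str, tuple[ImageVolume, SegmentationMask]]
    retest_pairs: dict[str, tuple[ImageVolume, SegmentationMask]]
    outcomes: dict[str, int]
    truth: dict[str, dict[str, float]]
    config: CohortConfig

    def __post_init__(self) -> None:
        missing = set(self.retest_pairs) - set(self.subjects)
        if missing:
            raise ValueError(f"retest ids without a subject: {sorted(missing)}")
        if set(self.outcomes) != set(self.subjects):
            raise ValueError("outcomes must be defined for every subject")

    def outcome_vector(self, ids: list[str] | None = None) -> np.ndarray:
        ids = self.subject_ids if ids is None else ids
        return np.array([self.outcomes[i] for i in ids], dtype=int)

    def write(self, outdir: str | Path) -> None:
        """Write per-subject NIfTI files, the outcome CSV and a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sid in self.subject_ids:
            img, msk = self.subjects[sid]
            img.to_nifti(outdir / f"{sid}_image.nii.gz")
            msk.to_nifti(outdir / f"{sid}_mask.nii.gz")
            if sid in self.retest_pairs:
                rimg, rmsk = self.retest_pairs[sid]
                rimg.to_nifti(outdir / f"{sid}_retest_image.nii.gz")
                rmsk.to_nifti(outdir / f"{sid}_retest_mask.nii.gz")
        pd.DataFrame(
            {"id": self.subject_ids, "outcome": [self.outcomes[i] for i in self.subject_ids]}
        ).to_csv(outdir / "outcomes.csv", index=False)
        manifest = {
            "config": asdict(self.config),
            "subjects": self.subject_ids,
            "retest_ids": sorted(self.retest_pairs),
            "truth": self.truth,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _ellipsoid_mask(shape, spacing, centre_mm, radii_mm) -> np.ndarray:
    grid = np.mgrid[[slice(0, n) for n in shape]].astype(np.float64)
    q = np.zeros(shape)
    for d in range(3):
        q += ((grid[d] * spacing[d] - centre_mm[d]) / radii_mm[d]) ** 2
    return q <= 1.0


def _smooth_texture(shape, spacing, sigma_mm, rng) -> np.ndarray:
    """Unit-variance band-limited random field (Gaussian-smoothed noise)."""
    raw = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(raw, sigma=[sigma_mm / s for s in spacing])
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _solve_intercept(score: np.ndarray, prevalence: float) -> float:
    """Intercept b0 such that mean sigmoid(b0 + score) equals prevalence."""

    def gap(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + score)))) - prevalence)

    return optimize.brentq(gap, -50.0, 50.0)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a deterministic synthetic cohort from a config."""
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    outcome_rng = np.random.default_rng(root.spawn(1)[0])

    shape, spacing = tuple(config.grid_shape), tuple(config.spacing_mm)
    centre0 = np.array([(n - 1) / 2.0 * s for n, s in zip(shape, spacing)])

    subject_ids, subjects, retest_pairs, truth = [], {}, {}, {}
    tex_latent = np.empty(config.n_subjects)
    irr_latent = np.empty(config.n_subjects)

    for i, seed_seq in enumerate(subject_seeds):
        rng = np.random.default_rng(seed_seq)
        sid = f"S{i:03d}"
        subject_ids.append(sid)

        base_r = rng.uniform(*config.tumor_radius_mm)
        radii = base_r * rng.uniform(0.8, 1.2, size=3)
        centre = centre0 + rng.uniform(-1.5, 1.5, size=3)
        ellipsoid = _ellipsoid_mask(shape, spacing, centre, radii)

        # latent boundary irregularity: contour-randomize the ellipsoid
        irregularity = rng.uniform(0.0, 1.0)
        irr_intensity = 2.0 * irregularity
        if irr_intensity > 0:
            fld = build_displacement_field(
                shape, spacing, (4.0, 4.0, 4.0),
                (irr_intensity,) * 3, int(rng.integers(2**31 - 1)))
            true_mask = randomize_contour(
                SegmentationMask(ellipsoid, spacing), fld).array
        else:
            true_mask = ellipsoid

        # latent texture amplitude
        tex_amp = config.texture_contrast * rng.uniform(0.5, 1.5)
        texture = _smooth_texture(shape, spacing, 1.5, rng) * tex_amp
        envelope = ndimage.gaussian_filter(
            true_mask.astype(np.float64), sigma=[1.0 / s for s in spacing])
        clean = envelope * (50.0 + texture)

        image = clean + config.noise_sd * rng.standard_normal(shape)
        mask = SegmentationMask(true_mask, spacing)
        subjects[sid] = (ImageVolume(image, spacing), mask)

        # retest pair: fresh noise, rigid shift, independent contour draw
        retest_img = ImageVolume(
            clean + config.noise_sd * rng.standard_normal(shape), spacing)
        if config.retest_shift_mm > 0:
            direction = rng.standard_normal(2)
            direction /= np.linalg.norm(direction)
            shift_px = (
                config.retest_shift_mm * direction[0] / spacing[0],
                config.retest_shift_mm * direction[1] / spacing[1],
                0.0,
            )
            retest_img, _ = apply_rigid(
                retest_img, mask, PerturbationSpec(shift_px, 0.0, 0))
        if config.retest_contour_intensity_mm > 0:
            fld = build_displacement_field(
                shape, spacing, (config.retest_contour_sigma_mm,) * 3,
                (config.retest_contour_intensity_mm,) * 3,
                int(rng.integers(2**31 - 1)))
            retest_mask = randomize_contour(mask, fld)
        else:
            retest_mask = mask.copy()
        retest_pairs[sid] = (retest_img, retest_mask)

        tex_latent[i] = tex_amp
        irr_latent[i] = irregularity
        truth[sid] = {
            "radius_mm": float(base_r),
            "texture_amplitude": float(tex_amp),
            "irregularity": float(irregularity),
        }

    # logistic outcome on standardized latents
    def z(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    score = config.effect_size * (z(tex_latent) + z(irr_latent)) / np.sqrt(2.0)
    b0 = _solve_intercept(score, config.outcome_prevalence)
    probs = 1.0 / (1.0 + np.exp(-(b0 + score)))
    draws = outcome_rng.uniform(size=config.n_subjects)
    outcomes = {sid: int(draws[i] < probs[i]) for i, sid in enumerate(subject_ids)}
    for i, sid in enumerate(subject_ids):
        truth[sid]["event_probability"] = float(probs[i])

    return SyntheticCohort(subject_ids, subjects, retest_pairs, outcomes, truth, config)


def split_cohort(
    cohort: SyntheticCohort,
    train_fraction: float = 0.6,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Outcome-stratified train/test split of subject ids.

    Prevalence is matched between the splits to within one subject per
    stratum; deterministic given the seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly inside (0, 1)")
    y = cohort.outcome_vector()
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError(
            f"each outcome stratum needs >= 2 members, got counts {counts.tolist()}")
    train_ids, test_ids = train_test_split(
        cohort.subject_ids, train_size=train_fraction,
        stratify=y, random_state=seed, shuffle=True)
    return list(train_ids), list(test_ids)
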