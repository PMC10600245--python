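"""Feature registry and whole-subject extraction.

A registry enumerates every feature implied by a preprocessing
configuration: the 14 shape features (mask-derived, original image
only), plus 18 first-order and 75 texture features for the original and
each filtered image.  With the standard protocol (5 LoG scales and 8
wavelet decompositions) that is 14 + 14 x 93 = 1316 features.

Descriptors serialize as ``"<image_label>|<class>|<name>"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..image import ImageVolume, SegmentationMask
from ..preprocessing import PreprocessConfig, discretize, filtered_images, resample_isotropic
from .firstorder import FIRSTORDER_NAMES, first_order_features
from .shape import SHAPE_NAMES, shape_features
from .texture import (
    GLCM_NAMES, GLDM_NAMES, GLRLM_NAMES, GLSZM_NAMES, NGTDM_NAMES,
    texture_features,
)

__all__ = [
    "FeatureDescriptor",
    "feature_registry",
    "registry_size",
    "extract_all",
    "extract_table",
]

CLASS_SIZES = {
    "shape": 14, "firstorder": 18, "glcm": 24, "glrlm": 16,
    "glszm": 16, "gldm": 14, "ngtdm": 5,
}

_TEXTURE_CLASSES = [
    ("glcm", GLCM_NAMES), ("glrlm", GLRLM_NAMES), ("glszm", GLSZM_NAMES),
    ("gldm", GLDM_NAMES), ("ngtdm", NGTDM_NAMES),
]


@dataclass(frozen=True)
class FeatureDescriptor:
    image_label: str
    feature_class: str
    name: str

    def __post_init__(self) -> None:
        if self.feature_class == "shape" and self.image_label != "original":
            raise ValueError("shape features are mask-derived: image_label must be 'original'")

    def __str__(self) -> str:
        return f"{self.image_label}|{self.feature_class}|{self.name}"

    @classmethod
    def from_string(cls, s: str) -> "FeatureDescriptor":
        label, fclass, name = s.split("|")
        return cls(label, fclass, name)


def feature_registry(config: PreprocessConfig) -> list[FeatureDescriptor]:
    """Ordered list of all feature descriptors for a configuration."""
    registry = [FeatureDescriptor("original", "shape", n) for n in SHAPE_NAMES]
    for label in config.image_labels:
        registry += [FeatureDescriptor(label, "firstorder", n) for n in FIRSTORDER_NAMES]
        for cls, names in _TEXTURE_CLASSES:
            registry += [FeatureDescriptor(label, cls, n) for n in names]
    return registry


def registry_size(config: PreprocessConfig) -> int:
    """Total feature count: 14 shape + 93 per (original + filtered) image."""
    per_image = CLASS_SIZES["firstorder"] + sum(
        CLASS_SIZES[c] for c, _ in _TEXTURE_CLASSES)
    return CLASS_SIZES["shape"] + len(config.image_labels) * per_image


def extract_all(
    image: ImageVolume,
    mask: SegmentationMask,
    config: PreprocessConfig | None = None,
) -> dict[str, float]:
    """Extract the complete feature vector of one (image, mask) pair.

    Applies the preprocessing chain (isotropic resampling, filter bank,
    per-image ROI discretization) and returns descriptor-string -> value.
    Non-finite values are kept as NaN, never silently dropped.
    """
    config = config or PreprocessConfig()
    img, msk = resample_isotropic(image, mask, config)
    voxel_vol = float(np.prod(msk.spacing_mm))

    values: dict[str, float] = {}
    for name, v in shape_features(msk).items():
        values[f"original|shape|{name}"] = v

    for label, filt in filtered_images(img, config).items():
        levels = discretize(filt, msk, config.bin_count)
        roi_values = filt.array[msk.array]
        roi_levels = levels[msk.array]
        for name, v in first_order_features(roi_values, roi_levels, voxel_vol).items():
            values[f"{label}|firstorder|{name}"] = v
        for key, v in texture_features(levels, config.bin_count).items():
            values[f"{label}|{key}"] = v

    expected = registry_size(config)
    assert len(values) == expected, (
        f"internal error: extracted {len(values)} features, registry says {expected}")
    return values


def extract_table(
    entries: list[tuple[str, int, ImageVolume, SegmentationMask]],
    config: PreprocessConfig | None = None,
) -> pd.DataFrame:
    """Extract a feature table from (subject_id, repeat_index, image, mask).

    Repeat index 0 is the unperturbed / test scan; >= 1 are perturbed or
    retest copies.  Returns a DataFrame indexed by (subject, repeat) with
    descriptor-string columns.
    """
    config = config or PreprocessConfig()
    rows, index = [], []
    for sid, rep, img, msk in entries:
        rows.append(extract_all(img, msk, config))
        index.append((sid, rep))
    table = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(
        index, names=["subject", "repeat"]))
    return table
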