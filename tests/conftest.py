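"""Shared fixtures: small geometric phantoms and a miniature cohort."""

import numpy as np
import pytest

from radrepeat.image import ImageVolume, SegmentationMask


def make_ball(radius_vox: float, shape=None, spacing=(1.0, 1.0, 1.0)) -> SegmentationMask:
    """Digital ball: voxel centres within radius of the grid centre."""
    if shape is None:
        n = int(2 * radius_vox + 7)
        shape = (n, n, n)
    c = [(n - 1) / 2.0 for n in shape]
    g = np.mgrid[[slice(0, n) for n in shape]].astype(float)
    r2 = sum(((g[d] - c[d]) * spacing[d]) ** 2 for d in range(3))
    return SegmentationMask(r2 <= radius_vox**2, spacing)


@pytest.fixture(scope="session")
def sphere20mm() -> SegmentationMask:
    """20 mm-diameter sphere at 1 mm isotropic spacing."""
    return make_ball(10.0)


@pytest.fixture(scope="session")
def noise_image20(sphere20mm) -> ImageVolume:
    rng = np.random.default_rng(42)
    return ImageVolume(rng.normal(50, 10, size=sphere20mm.shape),
                       sphere20mm.spacing_mm)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six-subject cohort for fast structural tests."""
    from radrepeat.synthetic import CohortConfig, generate_cohort

    return generate_cohort(CohortConfig(n_subjects=6, grid_shape=(24, 24, 24),
                                        tumor_radius_mm=(5.0, 7.0), seed=5))
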