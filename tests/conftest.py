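import numpy as np
import pytest

from opgpred.geometry import RegionMask
from opgpred.synthetic import CohortConfig, generate_cohort


def digital_disk(radius_vox: int, pad: int = 2) -> np.ndarray:
    """2D digital disk: pixels whose centers lie within radius of the center."""
    n = 2 * (radius_vox + pad) + 1
    c = n // 2
    yy, xx = np.mgrid[:n, :n]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_vox**2


def digital_cylinder(
    radius_mm: float, length_vox: int, spacing=(1.0, 1.0, 1.0), label="cyl"
) -> RegionMask:
    """3D digital cylinder along the last (axial) axis, voxel-center inclusion."""
    r_vox = radius_mm / spacing[0]
    n = int(2 * (np.ceil(r_vox) + 2) + 1)
    c = n // 2
    yy, xx = np.mgrid[:n, :n]
    disk = ((yy - c) ** 2 + (xx - c) ** 2) * spacing[0] * spacing[1] <= radius_mm**2
    mask = np.zeros((n, n, length_vox + 4), dtype=bool)
    for k in range(2, 2 + length_vox):
        mask[:, :, k] = disk
    return RegionMask(mask=mask, label=label, spacing_mm=spacing)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small full-fidelity cohort shared across tests (3 cases + 3 controls)."""
    cfg = CohortConfig(n_cases=3, n_controls=3, seed=7, grid_shape=(24, 24, 24))
    return generate_cohort(cfg)
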