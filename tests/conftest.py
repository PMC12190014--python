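import numpy as np
import pytest

from cd4pet.radiometrics import InjectionContext
from cd4pet.spatial import RegionMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ctx():
    """A 10 MBq injection at t=0 with the Cu-64 half-life."""
    return InjectionContext(injected_activity=1.0e7, injection_time=0.0)


def disk_mask(n: int, radius: float, spacing: float = 1.0,
              center=None) -> RegionMask:
    """Rasterized disk on an n x n grid (voxel-center containment)."""
    if center is None:
        c = (n - 1) / 2.0 * spacing
        center = (c, c)
    ii, jj = np.indices((n, n), dtype=float)
    r = np.hypot(ii * spacing - center[0], jj * spacing - center[1])
    return RegionMask(r <= radius, label="tumor", spacing=(spacing, spacing))


def ellipse_mask(shape, semi_axes, spacing=(1.0, 1.0)) -> RegionMask:
    """Rasterized axis-aligned ellipse centered on the grid."""
    a, b = semi_axes
    cy = (shape[0] - 1) / 2.0 * spacing[0]
    cx = (shape[1] - 1) / 2.0 * spacing[1]
    ii, jj = np.indices(shape, dtype=float)
    inside = ((ii * spacing[0] - cy) / a) ** 2 + ((jj * spacing[1] - cx) / b) ** 2 <= 1
    return RegionMask(inside, label="tumor", spacing=tuple(spacing))
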