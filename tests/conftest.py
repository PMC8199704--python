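import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from secr.dvh import DVH
from secr.rt_io import DoseGrid, GridGeometry, OrganMask

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture
def small_geometry() -> GridGeometry:
    return GridGeometry(origin=(0.0, 0.0, 0.0), spacing=(10.0, 10.0, 10.0), dims=(2, 1, 1))


@pytest.fixture
def two_voxel_dvh() -> DVH:
    """Two 1 cm^3 voxels at 0.5 and 1.5 Gy, bin width 1 Gy."""
    return DVH(
        organ="demo",
        bin_width=1.0,
        edges=np.array([0.0, 1.0, 2.0]),
        volumes=np.array([1.0, 1.0]),
    )


def uniform_dvh(dose: float, volume: float = 10.0, bin_width: float = 0.1) -> DVH:
    """Single-bin DVH whose occupied bin is centred exactly on `dose`."""
    lo = dose - bin_width / 2
    return DVH(
        organ="uniform",
        bin_width=bin_width,
        edges=np.array([lo, lo + bin_width]),
        volumes=np.array([volume]),
    )


def random_dose_and_mask(rng: np.random.Generator, n: int = 8):
    """Random n^3 dose grid and nonempty mask on a 1 mm grid."""
    geom = GridGeometry(origin=(0.0, 0.0, 0.0), spacing=(1.0, 1.0, 1.0), dims=(n, n, n))
    dose = DoseGrid(geom, rng.uniform(0.0, 5.0, size=geom.shape))
    membership = rng.random(geom.shape) < 0.4
    if not membership.any():
        membership[0, 0, 0] = True
    mask = OrganMask(geometry=geom, membership=membership, name="rand")
    return dose, mask
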