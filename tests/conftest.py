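import numpy as np
import pytest

from spherohca.geometry import AcquisitionGeometry
from spherohca.simulate import SpheroidPhenotypeParams, render_well


@pytest.fixture(scope="session")
def geometry():
    return AcquisitionGeometry()


@pytest.fixture(scope="session")
def clean_well(geometry):
    """Noise-free rendered well: 2000 cells, 12 pL/cell, perfect disk."""
    params = SpheroidPhenotypeParams(seeded_cells=2000, noise_sd=0.0)
    images, truth = render_well(params, geometry, time_days=0.0, seed=7)
    return params, images, truth


@pytest.fixture(scope="session")
def noisy_well(geometry):
    """Rendered well with the default read noise."""
    params = SpheroidPhenotypeParams(seeded_cells=2000)
    images, truth = render_well(params, geometry, time_days=0.0, seed=11)
    return params, images, truth


def disk_mask(radius_px: float, pad: int = 10) -> np.ndarray:
    """Rasterized disk for shape-statistic tests."""
    n = int(2 * radius_px + 2 * pad)
    yy, xx = np.mgrid[:n, :n]
    c = n / 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2


def ellipse_mask(a_px: float, b_px: float, pad: int = 10) -> np.ndarray:
    n = int(2 * max(a_px, b_px) + 2 * pad)
    yy, xx = np.mgrid[:n, :n]
    c = n / 2
    return (xx - c) ** 2 / a_px**2 + (yy - c) ** 2 / b_px**2 <= 1
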