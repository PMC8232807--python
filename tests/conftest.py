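import numpy as np
import pytest

from mriharm.core import AcquisitionSetting, ImageVolume
from mriharm.synthetic import default_field_strength_pair, generate_brain_volume


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def identity_setting():
    return AcquisitionSetting("ident", fov=24.0, matrix=64)


@pytest.fixture
def paired_settings():
    """Small-grid version of the default 1.5T-vs-3T pair."""
    return default_field_strength_pair(matrix=64)


@pytest.fixture(scope="session")
def small_brain_study():
    """One subject, both settings, small grid; reused across tests."""
    settings = default_field_strength_pair(matrix=64)
    return generate_brain_volume(settings, rois_per_tissue=5, seed=11)


def synthetic_brain_1d(rng, n=20000, wm=200.0, gm=120.0, csf=40.0, sigma=5.0):
    """Masked-intensity sample of a three-class T1-like brain."""
    sizes = (int(0.4 * n), int(0.45 * n), n - int(0.4 * n) - int(0.45 * n))
    vals = np.concatenate(
        [
            rng.normal(wm, sigma, sizes[0]),
            rng.normal(gm, sigma, sizes[1]),
            rng.normal(csf, sigma, sizes[2]),
        ]
    )
    rng.shuffle(vals)
    return vals


def volume_from_1d(vals, spacing=(1.0, 1.0, 1.0)):
    """Wrap a 1D intensity sample as a volume + full mask (shape-agnostic ops)."""
    n = vals.size
    side = int(np.ceil(n ** (1 / 3)))
    grid = np.zeros(side**3)
    grid[:n] = vals
    grid = grid.reshape(side, side, side)
    mask = np.zeros(side**3, dtype=bool)
    mask[:n] = True
    return ImageVolume(grid, spacing), mask.reshape(side, side, side)
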