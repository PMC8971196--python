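import numpy as np
import pytest

from myoph.ph_calibration import CalibrationCurve
from myoph.synthetic_data import (
    MonolayerPhantomSpec,
    default_h34580_curve,
    default_snarf_curve,
)


@pytest.fixture(scope="session")
def snarf_curve() -> CalibrationCurve:
    return default_snarf_curve()


@pytest.fixture(scope="session")
def h34580_curve() -> CalibrationCurve:
    return default_h34580_curve()


@pytest.fixture(scope="session")
def simple_curve() -> CalibrationCurve:
    """Rising curve with round parameters for hand calculations."""
    return CalibrationCurve(dye="toy", r_min=0.5, r_max=2.0, pKa=7.0, hill=1.0)


@pytest.fixture(scope="session")
def small_noiseless_field():
    """One noiseless monolayer field (single level, single isolation)."""
    spec = MonolayerPhantomSpec(
        image_shape=(512, 512),
        n_cells=60,
        n_isolations=1,
        pHe_levels=[7.0],
        photon_noise_sd=0.0,
        cell_jitter_sd=0.0,
        isolation_sd=0.0,
        seed=42,
    )
    from myoph.synthetic_data import generate_monolayer

    fields, truth = generate_monolayer(spec)
    return spec, fields[(7.0, 0)], truth


def make_disk_image(shape, centres, radii, value=200.0, background=0.0):
    """Utility: paint hard disks onto a constant background."""
    img = np.full(shape, background, dtype=float)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    for (cy, cx), r in zip(centres, radii):
        img[(rr - cy) ** 2 + (cc - cx) ** 2 <= r**2] = value
    return img
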