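import numpy as np
import pytest

import adipoquant as aq


@pytest.fixture(scope="session")
def calib():
    return aq.ScaleCalibration(1.0)


@pytest.fixture(scope="session")
def clean_fixture():
    """Noise-free, gap-free, speckle-free synthetic image with ground truth."""
    spec = aq.SyntheticSpec(
        n_cells=5, gap_probability=0.0, noise_sd=0.0, speckle_count=0, rng_seed=7
    )
    img, truth = aq.generate(spec)
    mask = aq.transform_pipeline(img)
    return spec, img, truth, mask


@pytest.fixture(scope="session")
def small_fixture():
    """128x128 fixture with small cells, used for exhaustive seed checks."""
    spec = aq.SyntheticSpec(
        height=128,
        width=128,
        n_cells=3,
        radius_range=(14.0, 19.0),
        membrane_thickness=3,
        gap_probability=0.0,
        noise_sd=0.0,
        speckle_count=0,
        rng_seed=5,
    )
    img, truth = aq.generate(spec)
    mask = aq.transform_pipeline(img)
    return spec, img, truth, mask


def center_seed(cell: aq.GroundTruthCell) -> aq.SeedPoint:
    return aq.SeedPoint(int(round(cell.center[0])), int(round(cell.center[1])))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
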