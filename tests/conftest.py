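import numpy as np
import pytest

from hogpipe import ImageParams, SimulationConfig, synthgen


@pytest.fixture(scope="session")
def bright_field():
    """A 20-cell field with homogeneous brightness and mild read noise:
    the regime where threshold segmentation is expected to work."""
    params = ImageParams(read_noise_sd=5.0, n_cells=20, radius_range=(9.0, 11.0))
    config = SimulationConfig(
        n_cells=2000, seed=42, eta2_int_true=0.01, eta2_ext_true=0.01, image_params=params
    )
    images, truth = synthgen.simulate_field_image(config)
    return images, truth


@pytest.fixture(scope="session")
def noiseless_field():
    """Single-cell field with no read/shot noise (exact conservation)."""
    params = ImageParams(n_cells=1)
    config = SimulationConfig(n_cells=2, seed=4, image_params=params)
    images, truth = synthgen.simulate_field_image(config)
    return images, truth


@pytest.fixture
def four_cell_table():
    """The tiny dual-reporter table used against the brute-force oracle."""
    import pandas as pd

    return pd.DataFrame(
        {"yfp": [100.0, 120.0, 80.0, 100.0], "tdtomato": [110.0, 110.0, 90.0, 90.0]}
    )
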