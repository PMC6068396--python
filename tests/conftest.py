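import numpy as np
import pytest

from vinehsi import (SceneConfig, SegmentationParams, make_sample_table,
                     make_signatures, render_scene)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def signatures():
    """Five well-separated 60-band variety signatures."""
    return make_signatures(5, 60, separation=0.5, seed=1)


@pytest.fixture(scope="session")
def clean_scene(signatures):
    """Noise-free scene under unit illumination: calibration is exactly invertible."""
    config = SceneConfig(n_columns=50, n_rows=40, n_bands=60, leaf_fraction=0.534,
                         illumination_drift=(1.0, 1.0), noise_sd=0.0, seed=3)
    return config, render_scene(config, signatures[0])


@pytest.fixture(scope="session")
def small_table():
    """5 varieties x 2 days x 10 samples, 40 bands; easily separable."""
    return make_sample_table(5, 2, 10, 40, separation=0.5, noise_sd=0.01, seed=2)


@pytest.fixture()
def default_params():
    return SegmentationParams()
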