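import numpy as np
import pytest

from psqi_geo.pipeline import WaterQualityModel
from psqi_geo.standards import default_standards
from psqi_geo.synthgen import SynthConfig, generate_dataset, miniature_standards


@pytest.fixture(scope="session")
def sanpin():
    return default_standards()


@pytest.fixture(scope="session")
def mini_standards():
    return miniature_standards()


@pytest.fixture(scope="session")
def small_config():
    """A reduced dataset for fast unit tests (not the study-scale default)."""
    return SynthConfig(n_points=80, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def fitted_small(small_dataset):
    """A fitted end-to-end model on the small dataset, shared across tests."""
    samples, truth = small_dataset
    r2 = {"pH": 0.6, "Hardness": 0.5, "NO3": -0.2, "Ca": 0.4}
    return WaterQualityModel.fit(
        samples, truth.standards, Q=1, r=2, seed=11, n_iter=80, r2_scores=r2
    )
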