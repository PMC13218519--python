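import numpy as np
import pytest

from trivasc.synthetic import SyntheticConfig, generate_roi
from trivasc.vessel_graph import build_network


@pytest.fixture(scope="session")
def config():
    return SyntheticConfig()


@pytest.fixture(scope="session")
def roi_sample(config):
    """One deterministic synthetic ROI shared across the suite."""
    return generate_roi(config, np.random.default_rng(20260922))


@pytest.fixture(scope="session")
def roi_network(roi_sample):
    return build_network(roi_sample.paths, roi=roi_sample.roi)


@pytest.fixture(scope="session")
def partition(config):
    return config.partition()
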