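import numpy as np
import pytest

from dermabss.simulator import SimulationConfig, simulate_image


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def sim_case(default_config):
    """One default simulated image with its ground truth and mixing matrix."""
    rng = np.random.default_rng(11)
    image, truth, mixing = simulate_image(default_config, rng)
    return image, truth, mixing


@pytest.fixture(scope="session")
def study_report():
    """The default 30-image study (shared across acceptance tests)."""
    from dermabss.pipeline import run_study
    return run_study(seed=202)
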