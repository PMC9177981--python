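import numpy as np
import pytest

from assistload import SimulationConfig, simulate_experiment

SMALL_CLASSES = (
    "null", "gluc_only", "cort_only", "additive",
    "synergistic", "antag_by_cort", "antag_by_gluc",
)


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study: 12 enhancer clusters, 40 genes per interaction class."""
    return SimulationConfig(
        seed=7,
        n_clusters=12,
        n_per_class={c: 40 for c in SMALL_CLASSES} | {"null": 200},
        n_housekeeping=100,
    )


@pytest.fixture(scope="session")
def small_exp(small_config):
    return simulate_experiment(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
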