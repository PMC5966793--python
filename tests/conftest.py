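import numpy as np
import pytest

import driftmem as dm
from driftmem.fitting import ModelConfig


@pytest.fixture(scope="session")
def pop_params():
    return dm.PopulationParams(gain=100.0, kappa=22.0)


@pytest.fixture(scope="session")
def lat_params():
    return dm.LatencyParams(threshold=7, residual_rate=9.2, offset=0.21,
                            survival_tau=0.2)


@pytest.fixture(scope="session")
def truth_params():
    return dm.default_truth_params("setsize_drift")


@pytest.fixture(scope="session")
def fast_config():
    return ModelConfig.fast()


@pytest.fixture(scope="session")
def clean_trials():
    """Small lapse-free, exclusion-free synthetic dataset (one participant)."""
    cfg = dm.GeneratorConfig(participants=1, trials_per_cell=10,
                             params=dm.default_truth_params("setsize_drift"),
                             p_swap=0.0, p_uniform=0.0, exclusion_rates={},
                             seed=11)
    trials, truth = dm.generate_dataset(cfg)
    return trials


@pytest.fixture(scope="session")
def messy_dataset():
    """Dataset with lapses and filter-violating trials, plus its ground truth."""
    cfg = dm.GeneratorConfig(participants=2, trials_per_cell=24, seed=5)
    return dm.generate_dataset(cfg)
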