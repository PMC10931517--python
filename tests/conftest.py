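import numpy as np
import pytest

from chronotell import ClockModel, ClockSimConfig, simulate_training


@pytest.fixture(scope="session")
def bundle_cfg():
    """Pinned study conditions: 12 genes, 6 timepoints, 12 instances,
    moderate correlated noise, one instance with a +2 h chronotype."""
    offsets = np.zeros(12)
    offsets[3] = 2.0
    return ClockSimConfig(chronotype_offsets=offsets, seed=1234)


@pytest.fixture(scope="session")
def bundle_es(bundle_cfg):
    return simulate_training(bundle_cfg)


@pytest.fixture(scope="session")
def train_es():
    """Plain training cohort (no chronotype) used by model-level tests."""
    return simulate_training(ClockSimConfig(seed=10))


@pytest.fixture(scope="session")
def fitted_model(train_es):
    return ClockModel().fit(train_es)
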