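import numpy as np
import pytest

from bcisim.controller import ControllerConfig
from bcisim.encoder import EnsembleParams, sample_ensemble
from bcisim.experiments import fit_reference_trajectory_model, generate_targets
from bcisim.geometry import default_start_pos


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def target_set():
    return generate_targets(33, seed=11)


@pytest.fixture(scope="session")
def start_pos():
    return default_start_pos()


@pytest.fixture(scope="session")
def short_cfg():
    return ControllerConfig.short_reach()


@pytest.fixture(scope="session")
def trajectory_model(target_set, start_pos, short_cfg):
    """Shared reference trajectory model (fit once per session)."""
    return fit_reference_trajectory_model(target_set, start_pos, short_cfg,
                                          rng=np.random.default_rng(77))


@pytest.fixture
def mixed_ensemble():
    """Small mixed ensemble covering every tuning kind and both noise models."""
    return sample_ensemble(10, 6, goal_kind="goal_gaussian", q_std=20.0,
                           params=EnsembleParams(), seed=5)
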