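import numpy as np
import pytest

from fishclim.demand import InverseAIDS
from fishclim.params import IaidsParams
from fishclim.pipeline import panel_to_stage_obs
from fishclim.synthetic import SyntheticConfig, gen_demand_history


@pytest.fixture(scope="session")
def noisefree_cfg():
    return SyntheticConfig(seed=7, share_noise_sd=0.0)


@pytest.fixture(scope="session")
def noisefree_panel(noisefree_cfg):
    return gen_demand_history(noisefree_cfg)


@pytest.fixture(scope="session")
def noisy_cfg():
    return SyntheticConfig(seed=42, n_months=120, share_noise_sd=0.01)


@pytest.fixture(scope="session")
def noisy_panel(noisy_cfg):
    return gen_demand_history(noisy_cfg)


@pytest.fixture(scope="session")
def noisefree_stage_obs(noisefree_cfg, noisefree_panel):
    return panel_to_stage_obs(noisefree_panel, noisefree_cfg.species_groups)


@pytest.fixture(scope="session")
def noisy_stage_obs(noisy_cfg, noisy_panel):
    return panel_to_stage_obs(noisy_panel, noisy_cfg.species_groups)


@pytest.fixture(scope="session")
def fitted_stage1_noisy(noisy_stage_obs):
    s1, _ = noisy_stage_obs
    return InverseAIDS().fit(s1["lnq"], s1["w"], labels=s1["labels"])


@pytest.fixture
def simple_params():
    """Hand-built admissible 3-good system."""
    gamma = np.array([
        [-0.10, 0.06, 0.04],
        [0.06, -0.09, 0.03],
        [0.04, 0.03, -0.07],
    ])
    return IaidsParams(alpha=np.array([0.5, 0.3, 0.2]),
                       beta=np.array([0.02, -0.015, -0.005]),
                       gamma=gamma)
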