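import numpy as np
import pytest

from phenodyn import GeneratorConfig, gen_colony_trajectories, gen_growth_rates


@pytest.fixture
def rewired_tracks():
    """300 adapted-phase trajectories (CV 0.3, 5% noise, hourly for 12 h)."""
    cfg = GeneratorConfig(seed=42, n_cells=300, mean_rate=np.log(2) / 8.4, cv=0.3, noise_cv=0.05)
    return gen_colony_trajectories(gen_growth_rates(cfg), cfg), cfg


@pytest.fixture
def noiseless_tracks():
    cfg = GeneratorConfig(seed=7, n_cells=50, mean_rate=np.log(2) / 8.4, cv=0.3, noise_cv=0.0)
    return gen_colony_trajectories(gen_growth_rates(cfg), cfg), cfg
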