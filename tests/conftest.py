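import numpy as np
import pytest

from epiturn.synth.expression import ExprSimConfig, simulate_expression
from epiturn.synth.tissue import TissueSimConfig, simulate_basal_dynamics


@pytest.fixture(scope="session")
def coupled_events():
    """A coupled simulation where every delamination triggers a division."""
    cfg = TissueSimConfig(
        field_size=(300, 300),
        init_density=0.5,
        delam_rate=0.02,
        coupling_prob=1.0,
        n_frames=40,
        frame_interval=6.0,
        seed=11,
    )
    return simulate_basal_dynamics(cfg)


@pytest.fixture(scope="session")
def trajectory_bundle():
    """A two-dataset expression simulation with a latent axis."""
    cfg = ExprSimConfig(
        n_cells={"c1": 220, "tenx": 280},
        depth_mean={"c1": 6000.0, "tenx": 2500.0},
        nb_dispersion=0.15,
        splicing_lag=0.1,
        sorted_threshold=0.5,
        cycling_fraction=0.15,
        seed=7,
    )
    return simulate_expression(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
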