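import numpy as np
import pytest

from flyforage.config import AgentSpec, ArenaConfig
from flyforage.kinematics import Trajectory
from flyforage.rlmodels import RLParams


@pytest.fixture
def arena() -> ArenaConfig:
    return ArenaConfig()


@pytest.fixture
def fq_params() -> RLParams:
    return RLParams(model="FQ", alpha=0.3, beta=6.0, bias=0.3)


@pytest.fixture
def rl_agent(fq_params) -> AgentSpec:
    return AgentSpec(kind="rl", rl_params=fq_params)


def make_traj(x, dt=0.05, y=None):
    """Trajectory from an x array sampled on a uniform grid."""
    x = np.asarray(x, float)
    t = np.arange(len(x)) * dt
    y = np.full_like(x, 2.5) if y is None else np.asarray(y, float)
    return Trajectory(time=t, x=x, y=y)


@pytest.fixture
def traj_factory():
    return make_traj
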