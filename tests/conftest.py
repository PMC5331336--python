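import numpy as np
import pytest
from hypothesis import settings

from iftflow.core import Trajectory
from iftflow.smtrack import ClassRules
from iftflow.synthdata import KineticsConfig, OpticsConfig

settings.register_profile("iftflow", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("iftflow")

DT = 0.15


@pytest.fixture
def rules() -> ClassRules:
    return ClassRules(dt_frame=DT)


@pytest.fixture
def kinetics() -> KineticsConfig:
    return KineticsConfig()


@pytest.fixture
def clean_optics() -> OpticsConfig:
    return OpticsConfig(shot_noise=False, background_rate=0.0)


def make_trajectory(x, dt: float = DT, t0: float = 0.0) -> Trajectory:
    x = np.asarray(x, dtype=float)
    t = t0 + np.arange(len(x)) * dt
    return Trajectory(t=t, x=x, y=np.zeros(len(x)), dt_frame=dt)


def line_trajectory(x0: float, v: float, duration: float, dt: float = DT,
                    L: float = 9000.0, tid: int = 0) -> Trajectory:
    n = int(duration / dt)
    t = np.arange(n) * dt
    x = np.clip(x0 + v * t, 0.0, L)
    return Trajectory(t=t, x=x, y=np.zeros(n), id=tid, dt_frame=dt)
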