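import numpy as np
import pytest

from stepgaze import synthetic_data as sd
from stepgaze.trial_io import GazeStream, MarkerTrajectory, StepGeometry


@pytest.fixture(scope="session")
def write_trial():
    """One fully rendered write-condition trial with ground truth."""
    return sd.simulate_trial(sd.condition_presets("write"), seed=101)


@pytest.fixture(scope="session")
def no_phone_trial():
    return sd.simulate_trial(sd.condition_presets("no_phone"), seed=202)


@pytest.fixture()
def step():
    return StepGeometry(edge_x=4.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_traj(name, xyz, rate=100.0):
    return MarkerTrajectory(name=name, xyz=np.asarray(xyz, float), rate=rate)


def make_stream(labels, rate=30.0):
    return GazeStream(labels=np.asarray(labels, dtype=object), rate=rate)
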