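import dataclasses

import pytest
from hypothesis import HealthCheck, settings

import midwdemand as md
from midwdemand.params import ParameterTrajectory

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def packaged():
    common, scenarios, key = md.packaged_parameters()
    return common, scenarios, key


@pytest.fixture(scope="session")
def common(packaged):
    return packaged[0]


@pytest.fixture(scope="session")
def scenarios(packaged):
    return packaged[1]


@pytest.fixture(scope="session")
def key(packaged):
    return packaged[2]


@pytest.fixture(scope="session")
def casemix():
    return md.packaged_casemix()


def with_constant(params, trajectory_id, value, unit=None):
    """Copy of ``params`` with one trajectory replaced by a constant."""
    traj = params.trajectories[trajectory_id]
    new = dict(params.trajectories)
    new[trajectory_id] = ParameterTrajectory(
        id=trajectory_id,
        unit=unit or traj.unit,
        anchors={params.base_year: value},
        rule="constant",
    )
    return dataclasses.replace(params, trajectories=new)


@pytest.fixture
def constant_setter():
    return with_constant
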