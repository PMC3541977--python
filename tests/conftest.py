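import pytest
from hypothesis import HealthCheck, settings

from vfmchart import (
    build_vfm_points,
    load_example_points_system,
    load_example_technologies,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ps():
    """The bundled illustrative points system (five benefit dimensions)."""
    return load_example_points_system()


@pytest.fixture(scope="session")
def techs(ps):
    """The bundled 18 illustrative technologies."""
    return load_example_technologies(ps)


@pytest.fixture(scope="session")
def points(ps, techs):
    return build_vfm_points(techs, ps)


# ids removed in the first deliberation round of the worked example, and the
# frontier the committee then faces
FIRST_ROUND = ("t1", "t2", "t4", "t6")
SECOND_FRONTIER = ("t16", "t14", "t7", "t5", "t3")
THIRD_FRONTIER = ("t18", "t15", "t11", "t9", "t8")
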