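import pytest

from groupforage import GroupStrategy, GroupType, ModelParams, PRESETS


@pytest.fixture(scope="session")
def standard() -> ModelParams:
    """Baseline parameter set: F_max=3, c0=4, M_b=0.1, o_M=1."""
    return PRESETS["standard"]


@pytest.fixture(scope="session")
def presets() -> dict[str, ModelParams]:
    return PRESETS


@pytest.fixture
def solitary() -> GroupStrategy:
    return GroupStrategy(GroupType.EGALITARIAN, 1)
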