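import pytest

from edtsim import default_group_params

BASE_SEED = 0


@pytest.fixture(scope="session")
def group_params():
    return default_group_params()


@pytest.fixture(scope="session")
def group_by_label(group_params):
    return {gp.group: gp for gp in group_params}
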