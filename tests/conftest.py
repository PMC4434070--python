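import pytest

from monodde import reference_scenarios


@pytest.fixture(scope="session")
def scenarios():
    """The named reference scenarios, computed once per session."""
    return {sc.name: sc for sc in reference_scenarios()}


@pytest.fixture(scope="session")
def scenario_list():
    return reference_scenarios()
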