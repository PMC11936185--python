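import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def deck():
    from psmcea.synthetic import make_base_deck

    return make_base_deck()


@pytest.fixture(scope="session")
def base_result(deck):
    from psmcea.analysis import run_base_case

    return run_base_case(deck)
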