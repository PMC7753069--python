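import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def germline():
    from ighjkit import load_germline_config

    return load_germline_config()


@pytest.fixture(scope="session")
def consensus():
    from ighjkit import ConsensusSet

    return ConsensusSet()


@pytest.fixture(scope="session")
def efficiency_table():
    from ighjkit import build_default_efficiency_table

    return build_default_efficiency_table()


@pytest.fixture(scope="session")
def j_genes(germline):
    return {n: g for n, g in germline.items() if n.startswith("IGHJ")}
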