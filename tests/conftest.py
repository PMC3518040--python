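import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from apoptonet.models import (  # noqa: E402
    build_bcl2_extension,
    build_vcp_extension,
    build_yeast_network,
)


@pytest.fixture(scope="session")
def yeast():
    return build_yeast_network()


@pytest.fixture(scope="session")
def bcl2():
    return build_bcl2_extension()


@pytest.fixture(scope="session")
def vcp():
    return build_vcp_extension()
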