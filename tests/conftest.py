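import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from gdgtkit import canonical_descriptor, default_library  # noqa: E402


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def ext_igtgt0():
    return canonical_descriptor("GTGT", extensions=1)


@pytest.fixture(scope="session")
def diext_igtgt0():
    return canonical_descriptor("GTGT", extensions=2)


@pytest.fixture(scope="session")
def ext_igdgt0():
    return canonical_descriptor("GDGT", extensions=1)
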