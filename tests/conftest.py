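import pytest
from hypothesis import HealthCheck, settings

from cemeta import load_records

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def table():
    """The packaged 17-observation reference dataset."""
    return load_records("fixture:mastaleru2025")
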