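import pytest
from hypothesis import HealthCheck, settings

from wrkykit import io_formats

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def family():
    """The curated 58-member family table bundled with the package."""
    return io_formats.read_family_table()


@pytest.fixture(scope="session")
def reference_set():
    """Synthetic stand-ins for the 12 subgroup reference proteins."""
    from wrkykit import synthetic_data

    return synthetic_data.gen_reference_set()
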