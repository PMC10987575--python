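import pytest
from hypothesis import settings

from pamg.catalog import load_catalog

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def catalog():
    return load_catalog()
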