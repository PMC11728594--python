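import pytest

from gwrisk.io import load_exposure, load_site
from gwrisk.registry import default_chemicals


@pytest.fixture(scope="session")
def chems():
    return default_chemicals()


@pytest.fixture(scope="session")
def exposure():
    return load_exposure()


@pytest.fixture(scope="session")
def site():
    return load_site()
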