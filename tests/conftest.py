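import pytest

from bonevpd.fixtures import preset_parameters


@pytest.fixture(scope="session")
def cortical():
    return preset_parameters("cortical")


@pytest.fixture(scope="session")
def trabecular():
    return preset_parameters("trabecular")
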