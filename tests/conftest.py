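import pytest

from phonosim import load_language


@pytest.fixture(scope="session")
def sv():
    return load_language("sv")


@pytest.fixture(scope="session")
def no():
    return load_language("no")


@pytest.fixture(scope="session")
def en():
    return load_language("en")


@pytest.fixture(scope="session")
def profiles(sv, no, en):
    return {"sv": sv, "no": no, "en": en}
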