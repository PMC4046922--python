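import pytest

from paleomt import load_ppnb_profiles, synthetic_reference


@pytest.fixture(scope="session")
def ref():
    return synthetic_reference()


@pytest.fixture(scope="session")
def profiles():
    return load_ppnb_profiles()
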