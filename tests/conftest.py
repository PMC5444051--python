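import pytest
from hypothesis import settings

from causalminer import default_lexicon, default_vocabulary

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def vocab():
    return default_vocabulary()
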