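import pytest

from opmbio import fixtures


@pytest.fixture(scope="session")
def transcription():
    return fixtures.build_transcription_model()


@pytest.fixture(scope="session")
def erroneous():
    return fixtures.build_transcription_erroneous()


@pytest.fixture()
def toy_binding():
    return fixtures.build_toy_binding()


@pytest.fixture(scope="session")
def tfiif_tfiib():
    return fixtures.build_tfiif_tfiib_structure()
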