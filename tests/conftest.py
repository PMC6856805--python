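import pytest

from pharmera.synthetic import mpa_fixture


@pytest.fixture(scope="session")
def fx():
    """The bundled mycophenolic-acid constants."""
    return mpa_fixture()
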