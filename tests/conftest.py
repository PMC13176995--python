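import pytest

from platkin.constants import DEFAULT_CONSTANTS
from platkin.synthetic import builtin_profiles


@pytest.fixture(scope="session")
def profiles():
    """The packaged literature free-energy profiles, loaded once."""
    return builtin_profiles()


@pytest.fixture(scope="session")
def consts():
    return DEFAULT_CONSTANTS
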