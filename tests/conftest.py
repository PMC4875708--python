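import pytest

from gpdcat import load_default_bank


@pytest.fixture(scope="session")
def bank():
    """The packaged 52-item bank (nominal intercept metric)."""
    return load_default_bank()


@pytest.fixture(scope="session")
def admin_bank(bank):
    """The bank in the slope-difficulty metric used for administration."""
    return bank.as_administered()
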