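import pytest

from pedkit.synthetic import fixtures

FIXTURE_NAMES = ("trio", "nuclear", "first_cousins", "sib_mating_loop",
                 "cross_generation", "twins", "two_families")


@pytest.fixture(scope="session")
def fx():
    """The canonical fixture pedigrees, built once per session."""
    return fixtures()
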