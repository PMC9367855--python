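import pytest
from hypothesis import settings

from promread.battery import rows_from_reference

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")
from promread.synthetic import generate_battery_fixture
from promread.wordlist import expand_easy_list, load_default_easy_list


@pytest.fixture(scope="session")
def easy_list():
    """The bundled (synthetic, ~3000-form) easy list, expanded."""
    return load_default_easy_list()


@pytest.fixture()
def tiny_easy_list():
    """A hand-sized list so no particular bundled list version is load-bearing."""
    return expand_easy_list(
        ["thing", "kid", "write", "run", "happy", "cat", "sun", "play"],
        irregulars={"write": ["wrote", "written"], "run": ["ran"]},
        provenance="tiny test list",
    )


@pytest.fixture(scope="session")
def reference_battery():
    """The packaged reference battery in age-passthrough form."""
    return rows_from_reference(generate_battery_fixture())
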