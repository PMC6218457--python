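import pytest

from projectome.synthetic import make_atlas


@pytest.fixture(scope="session")
def atlas_bundle():
    """The default synthetic two-hemisphere atlas (shared, read-only)."""
    return make_atlas()
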