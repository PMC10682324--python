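import pytest
from hypothesis import settings as hyp_settings

from cad_breakeven import load_corpus, load_settings

hyp_settings.register_profile("default", derandomize=True, deadline=None)
hyp_settings.load_profile("default")


@pytest.fixture(scope="session")
def corpus():
    """The packaged evidence table: 8 published reader-timing arm pairs."""
    return load_corpus("table1")


@pytest.fixture(scope="session")
def settings():
    """Default country/pricing/scenario configuration."""
    return load_settings("default")
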