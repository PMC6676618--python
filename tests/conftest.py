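import pytest

from fragcoord import (
    build_fixture_corpus,
    build_library,
    builtin_ring_templates,
)


@pytest.fixture(scope="session")
def fixture_corpus():
    """Each fixture molecule three times, no jitter."""
    return build_fixture_corpus(n_copies=3, jitter_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def fixture_library(fixture_corpus):
    return build_library(fixture_corpus)


@pytest.fixture(scope="session")
def ring_templates():
    return builtin_ring_templates()
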