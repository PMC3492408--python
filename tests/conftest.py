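import pytest

from ryrmap import builtin_patterns
from ryrmap.fixtures import (
    published_exclusions,
    published_fragments,
    published_motif_spans,
    published_topology,
)
from ryrmap.synthetic_scaffold import scaffold_sequence


@pytest.fixture(scope="session")
def scaffold():
    """The deterministic synthetic RyR1-like scaffold sequence."""
    return scaffold_sequence()


@pytest.fixture(scope="session")
def patterns():
    return builtin_patterns()


@pytest.fixture(scope="session")
def fixture_fragments():
    return published_fragments()


@pytest.fixture(scope="session")
def fixture_topology():
    return published_topology()


@pytest.fixture(scope="session")
def fixture_exclusions():
    return published_exclusions()


@pytest.fixture(scope="session")
def fixture_motif_spans():
    return published_motif_spans()
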