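import pytest

from degenmix.core import DesignRules
from degenmix.fixtures import benchmark_panel, recovery_family


@pytest.fixture(scope="session")
def rules():
    return DesignRules()


@pytest.fixture(scope="session")
def panel():
    """The synthetic 24-taxon validation panel (seed 0)."""
    return benchmark_panel(0)


@pytest.fixture(scope="session")
def recovery():
    """Seed-fixed planted-block family: (alignment, truth, tree)."""
    return recovery_family(1)
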