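import pytest

from plastidcheck.fixtures import bundled_module_catalog
from plastidcheck.kegg_modules import KOProfile, parse_module_definition


@pytest.fixture(scope="session")
def catalog():
    return bundled_module_catalog()


@pytest.fixture(scope="session")
def toy_modules():
    """Tiny hand-parsed modules covering the grammar features."""
    return {
        "and_of_steps": parse_module_definition("M_toy1", "K00001 K00002"),
        "or_step": parse_module_definition("M_toy2", "(K00001,K00003) K00002"),
        "complex": parse_module_definition("M_toy3", "K00001+K00002"),
    }


@pytest.fixture
def small_profile():
    return KOProfile("g1", {"K00001": 3, "K00002": 2, "K00003": 5})
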