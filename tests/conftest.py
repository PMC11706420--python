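import pytest

import aopbpk as a


@pytest.fixture(scope="session")
def phys():
    return a.default_physiology()


@pytest.fixture(scope="session")
def drugs():
    return a.all_fixtures()


@pytest.fixture(scope="session")
def esf_on():
    return a.ESFPolicy()


@pytest.fixture(scope="session")
def esf_off():
    return a.ESFPolicy.disabled()


@pytest.fixture(scope="session")
def ziprasidone(drugs):
    return drugs["ziprasidone"]


@pytest.fixture(scope="session")
def bottom_up(drugs, phys, esf_on):
    """ESF-supported bottom-up pathway networks for all six drugs."""
    return {
        name: a.assemble_pathways(c, phys, source="HLM+HLC", esf=esf_on)
        for name, c in drugs.items()
    }
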