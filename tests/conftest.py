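import pytest

from igxchange import load_references


@pytest.fixture(scope="session")
def refs():
    return load_references()


@pytest.fixture(scope="session")
def igg1(refs):
    return refs["IgG1-CH3"]
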