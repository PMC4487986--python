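import pytest

from cnvortho import datasets


@pytest.fixture(scope="session")
def region_map():
    return datasets.load_region_map()


@pytest.fixture(scope="session")
def conservation_table():
    return datasets.load_conservation_table()


@pytest.fixture(scope="session")
def placements():
    return datasets.load_placements()
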