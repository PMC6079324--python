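import pytest

from drgcap import (
    fixture_path,
    read_delivery_table,
    read_funding_table,
    read_region_map,
)


@pytest.fixture(scope="session")
def table1():
    """The 2016 Northern Norway delivery counts per trust per DRG."""
    return read_delivery_table(fixture_path("table1.csv"))


@pytest.fixture(scope="session")
def table2():
    """The 2016 actual DRG funding per trust (EUR), split CS/vaginal."""
    return read_funding_table(fixture_path("table2.csv"))


@pytest.fixture(scope="session")
def regions():
    """Southern (Helgeland, Nordland) / northern (University, Finnmark) split."""
    return read_region_map(fixture_path("regions.csv"))
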