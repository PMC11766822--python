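import pytest

from steroscreen import (build_profiles, descriptor_table, load_fixture,
                         registry_structures)


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table3():
    """(records, reference ligands) for the affinity fixture."""
    return load_fixture("table3")


@pytest.fixture(scope="session")
def structures():
    return registry_structures()


@pytest.fixture(scope="session")
def profiles(table1, table3):
    records, reference = table3
    return build_profiles(table1, records, reference)


@pytest.fixture(scope="session")
def desc_frame(structures):
    """Internally computed descriptors for the 37 bundled steroids."""
    return descriptor_table(structures)
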