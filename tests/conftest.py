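import pytest

from ssmc11 import (
    default_probe_registry,
    load_cytobands,
    load_packaged_cohort,
)
from ssmc11.dosage import build_dosage_map


@pytest.fixture(scope="session")
def cytobands():
    return load_cytobands()


@pytest.fixture(scope="session")
def anchor(cytobands):
    return cytobands.centromere_anchor


@pytest.fixture(scope="session")
def registry():
    return default_probe_registry()


@pytest.fixture(scope="session")
def table1():
    return load_packaged_cohort("table1")


@pytest.fixture(scope="session")
def table2():
    return load_packaged_cohort("table2")


@pytest.fixture(scope="session")
def table3():
    return load_packaged_cohort("table3")


@pytest.fixture(scope="session")
def table4():
    return load_packaged_cohort("table4")


@pytest.fixture(scope="session")
def evidence():
    return load_packaged_cohort("evidence")


@pytest.fixture(scope="session")
def full_cohort(table1, table2):
    return table1 + table2


@pytest.fixture(scope="session")
def dosage_map(table3, table4, evidence, anchor):
    return build_dosage_map(table3, table4, evidence, anchor)
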