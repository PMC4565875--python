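import pytest
from hypothesis import settings

from isofine import DEFAULT_TABLE, ChemicalFormula, parse_formula

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def table():
    return DEFAULT_TABLE


@pytest.fixture(scope="session")
def oracle_table():
    """Plain-tuple view of the pinned isotope table for the brute-force oracle."""
    return {
        el: [(r.mass, r.abundance, r.neutron_offset) for r in recs]
        for el, recs in DEFAULT_TABLE.records.items()
    }


@pytest.fixture(scope="session")
def bsa():
    return parse_formula("C2934H4615N781O897S39")


@pytest.fixture(scope="session")
def chnos_small():
    """A small molecule containing all five elements (every count >= 2)."""
    return ChemicalFormula({"C": 2, "H": 2, "N": 2, "O": 2, "S": 2})
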