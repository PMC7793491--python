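import numpy as np
import pytest

from tspc4 import (
    AtomSelection,
    assign_regions,
    build_cc_pair_topology,
    parse_imotif_notation,
    select_atoms,
)
from tspc4.synthetic import make_toy_imotif_structure


@pytest.fixture(scope="session")
def ccct3():
    return parse_imotif_notation("d[(CCCTTT)3CCC]", name="CCCT3")


@pytest.fixture(scope="session")
def cccta2():
    return parse_imotif_notation("d[(CCCTAA)3CCC]", name="CCCTA2")


@pytest.fixture(scope="session")
def ccct3_regions(ccct3):
    return assign_regions(ccct3)


@pytest.fixture(scope="session")
def ccct3_topology(ccct3):
    return build_cc_pair_topology(ccct3)


@pytest.fixture(scope="session")
def toy_structure(ccct3):
    return make_toy_imotif_structure(ccct3)


@pytest.fixture(scope="session")
def whole_sel(toy_structure, ccct3_regions):
    return select_atoms(toy_structure, AtomSelection(region="whole"), ccct3_regions)
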