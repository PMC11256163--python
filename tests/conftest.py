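import pytest

from betagraft.fibril_geometry import detect_rung_offset
from betagraft.structure_io import extract_sequence
from betagraft.surface_analysis import (
    backbone_cbeta_reference_maxima,
    classify_exposure,
    compute_sasa,
)
from betagraft.synthetic_fixtures import make_het_s_scaffold


@pytest.fixture(scope="session")
def scaffold():
    """Synthetic idealized HET-s(218-289) two-rung beta-solenoid model."""
    return make_het_s_scaffold()


@pytest.fixture(scope="session")
def scaffold_seq(scaffold):
    return extract_sequence(scaffold, "A")


@pytest.fixture(scope="session")
def rung_map(scaffold):
    return detect_rung_offset(scaffold, "A")


@pytest.fixture(scope="session")
def cbeta_reference():
    """Relative-SASA reference maxima for backbone+Cβ models."""
    return backbone_cbeta_reference_maxima()


@pytest.fixture(scope="session")
def scaffold_exposure(scaffold, cbeta_reference):
    return classify_exposure(compute_sasa(scaffold, reference_max=cbeta_reference))
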