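import pytest

from strtwell.plate_layout import default_layout, generate_barcode_set
from strtwell.synthetic_data import SimulationConfig, make_toy_reference


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def barcode_set():
    return generate_barcode_set()


@pytest.fixture(scope="session")
def toy_reference():
    """Small two-chromosome reference with 12 genes, no repeats."""
    return make_toy_reference(SimulationConfig(seed=42, n_genes=12))


@pytest.fixture(scope="session")
def toy_reference_with_repeats():
    """Reference with duplicated exonic 45-mers recorded in the repeat BED."""
    return make_toy_reference(SimulationConfig(seed=43, n_genes=12, n_repeat_sites=3))
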