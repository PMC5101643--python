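import pytest

from athcnv.locus import default_locus_map
from athcnv.simulate import PanelConfig, simulate_panel, simulate_reference


@pytest.fixture(scope="session")
def locus_map():
    return default_locus_map()


@pytest.fixture(scope="session")
def reference_and_locus():
    """Synthetic reference segment with the LCR backbone attached."""
    return simulate_reference(seed=1)


@pytest.fixture(scope="session")
def noiseless_config():
    return PanelConfig(mlpa_noise_cv=0.0, sample_scale_cv=0.0)


@pytest.fixture(scope="session")
def default_panel():
    """Study-sized truth panel (189 accessions, study genotype mix)."""
    return simulate_panel(PanelConfig(), seed=2)


@pytest.fixture(scope="session")
def panel_truth(default_panel):
    return {p.accession_id: p for p in default_panel}
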