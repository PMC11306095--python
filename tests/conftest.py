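import numpy as np
import pytest

from cytoqtl.synth import PanelConfig, generate_panel


@pytest.fixture(scope="session")
def default_panel():
    """Full-size panel at study-design defaults (seed 0)."""
    return generate_panel(PanelConfig(seed=0))


@pytest.fixture(scope="session")
def small_panel():
    """Small panel for fast scan-stage tests."""
    cfg = PanelConfig(n_strains=24, n_discovery=14, n_loci=80, n_genes=20,
                      n_chromosomes=2, n_cell_types=3, n_cis_qtl=1,
                      n_trans_qtl=1, seed=3)
    return generate_panel(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
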