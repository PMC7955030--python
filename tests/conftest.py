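import numpy as np
import pytest

from mregulome import synthetic_data as synth
from mregulome.core_io import compute_ld_matrix


@pytest.fixture(scope="session")
def default_cfg():
    return synth.SimConfig(seed=7)


@pytest.fixture(scope="session")
def default_panel(default_cfg):
    return synth.simulate_ld_genotypes(default_cfg)


@pytest.fixture(scope="session")
def default_ld(default_panel):
    return compute_ld_matrix(default_panel)


@pytest.fixture(scope="session")
def default_locus(default_cfg, default_panel):
    """hqtl, eqtl, gwas, truth for the default planted chain."""
    return synth.simulate_summary_chain(default_cfg, default_panel)


@pytest.fixture(scope="session")
def default_landscape(default_cfg):
    return synth.simulate_regulatory_landscape(default_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
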