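import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from plastocomp import SimulationConfig, simulate_family


@pytest.fixture(scope="session")
def family():
    """One default-scale simulated family shared across tests."""
    records, truth = simulate_family(SimulationConfig(seed=11))
    return records, truth


@pytest.fixture(scope="session")
def small_family():
    """A reduced family (fast repeat scans and alignments)."""
    cfg = SimulationConfig(seed=23, lsc_len=4000, ir_len=1200, ssc_len=1000,
                           n_lsc_genes=5, n_ir_genes=2, n_ssc_genes=1,
                           gene_spacer=250)
    records, truth = simulate_family(cfg)
    return cfg, records, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
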