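import numpy as np
import pandas as pd
import pytest

from dentist import ReferencePanel, SimConfig, simulate_panel_pair


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_panel():
    """A hand-built 6-sample, 4-variant panel with known dosages."""
    geno = np.array(
        [
            [0, 1, 2, 0],
            [1, 1, 2, 0],
            [2, 0, 1, 1],
            [0, 2, 0, 1],
            [1, 1, 1, 2],
            [2, 0, 2, 0],
        ],
        dtype=np.int8,
    )
    variants = pd.DataFrame(
        {
            "id": ["rs1", "rs2", "rs3", "rs4"],
            "chrom": "1",
            "pos": [1000, 2000, 3000, 4000],
            "a1": ["A", "C", "G", "T"],
            "a2": ["G", "T", "A", "C"],
        }
    )
    return ReferencePanel(genotypes=geno, variants=variants)


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated GWAS panel pair shared across tests."""
    cfg = SimConfig(n_gwas=2000, n_ref=2000, m=600, m_causal=10, seed=7)
    rng = np.random.default_rng(cfg.seed)
    gwas, ref, truth = simulate_panel_pair(cfg, rng)
    return cfg, gwas, ref, rng
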