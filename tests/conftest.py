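import numpy as np
import pytest

import celltype_perturb as cp
from celltype_perturb.config import SimConfig


@pytest.fixture(scope="session")
def null_sim():
    """Small null dataset (no planted effects), QC'd and normalized."""
    cfg = SimConfig(seed=10, n_cell_types=2, cells_per_type_per_genotype=150,
                    n_genes=500, frac_de_vulnerable=0.0, frac_de_other=0.0)
    adata, truth = cp.simulate_counts(cfg)
    adata = cp.qc_pipeline(adata, min_genes=50)
    return adata, truth, cfg


@pytest.fixture(scope="session")
def planted_sim():
    """Dataset with strong planted effects in one vulnerable population."""
    cfg = SimConfig(seed=3, n_cell_types=2, cells_per_type_per_genotype=300,
                    n_genes=1000, frac_de_vulnerable=0.08, frac_de_other=0.0,
                    lfc_mean=1.2, lfc_sd=0.15, vulnerable_type="pop01")
    adata, truth = cp.simulate_counts(cfg)
    adata = cp.qc_pipeline(adata, min_genes=50)
    return adata, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
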