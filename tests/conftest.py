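import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from sctfscreen import CountMatrix, TFTargetModel
from sctfscreen.simulate import SimConfig, simulate_toe


@pytest.fixture(scope="session")
def default_sim():
    """The study-conditions simulation: 3,000 cells x 2,000 genes, 20 planted
    targets with beta=1.5, 60% transfection, seed 1."""
    return simulate_toe(SimConfig(seed=1))


@pytest.fixture(scope="session")
def default_fit(default_sim):
    m, truth = default_sim
    res = TFTargetModel(m, tf_gene="TF").fit(seed=1)
    return res, truth


@pytest.fixture(scope="session")
def small_sim():
    """Scaled-down simulation for cheap end-to-end checks."""
    cfg = SimConfig(n_cells=800, n_genes=500, n_targets=10, seed=7)
    return simulate_toe(cfg)


def make_count_matrix(counts, mito_mask=None, prefix="G"):
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    genes = pd.DataFrame(
        {
            "gene_id": [f"{prefix}{j:04d}" for j in range(n_genes)],
            "gene_name": [f"{prefix}{j:04d}" for j in range(n_genes)],
        }
    )
    return CountMatrix(
        counts=sparse.csr_matrix(counts),
        barcodes=[f"BC{i:05d}" for i in range(n_cells)],
        genes=genes,
        mito_mask=mito_mask,
    )


@pytest.fixture
def matrix_factory():
    return make_count_matrix
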