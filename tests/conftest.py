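import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from scstate.io_formats import CountMatrix
from scstate.synthetic import default_fixture, simulate


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """2 genes x 2 cells with entries (0,0)=3 and (1,1)=5."""
    return CountMatrix(
        genes=["geneA", "geneB"],
        barcodes=["cell1", "cell2"],
        counts=sparse.csc_matrix(np.array([[3, 0], [0, 5]])),
        sample_id="tiny",
    )


@pytest.fixture(scope="session")
def sim_run():
    """One default-fixture simulation shared across the session."""
    cfg = default_fixture(seed=11)
    matrices, cells, truth = simulate(cfg)
    return cfg, matrices, cells, truth


@pytest.fixture(scope="session")
def sim_norm(sim_run):
    """Merged and log-normalized expression for the shared simulation."""
    from scstate.annotate import log_normalize

    cfg, matrices, cells, truth = sim_run
    merged = CountMatrix.concat(matrices)
    assert merged.barcodes == cells["barcode"].tolist()
    return log_normalize(merged)


def random_count_matrix(rng: np.random.Generator, n_genes: int, n_cells: int) -> CountMatrix:
    dense = rng.poisson(0.5, size=(n_genes, n_cells))
    return CountMatrix(
        genes=[f"g{i}" for i in range(n_genes)],
        barcodes=[f"c{i}" for i in range(n_cells)],
        counts=sparse.csc_matrix(dense),
        sample_id="rand",
    )
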